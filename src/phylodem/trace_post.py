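"""Post-processing of mutation-scaled coalescent MCMC traces.

Reads tab-separated trace files (the G-PhoCS output dialect: a header row of
parameter names — ``theta_<pop>``, ``tau_<node>``, ``m_<source>-><target>``
— and one numeric row per retained sample), applies per-chain burn-in,
computes highest-posterior-density intervals and effective sample sizes,
screens migration bands by whether the 95% HPD of m is bounded away from
zero, and converts mutation-scaled posteriors to absolute units by Monte
Carlo calibration draws:

    N_e = θ / (4μ)          individuals
    T   = (τ / μ) · g       years
    2Nm = m · θ_target / 2  migrant gene copies per generation

with one independent (generation time g, mutation rate μ) pair drawn per
posterior sample, so calibration uncertainty propagates into every interval.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographyModel, ScaleConfig

__all__ = [
    "PosteriorTrace",
    "ConvertedPosterior",
    "IntervalSummary",
    "read_trace",
    "hpd_interval",
    "effective_sample_size",
    "draw_calibrations",
    "convert_sample",
    "monte_carlo_convert",
    "summarize_posterior",
    "screen_migration_bands",
    "DEFAULT_ROLE_PATTERNS",
]

# column-name → role classification; configurable per trace dialect
DEFAULT_ROLE_PATTERNS: dict[str, str] = {
    "theta": r"^theta[_.](?P<id>.+)$",
    "tau": r"^tau[_.](?P<id>.+)$",
    "m": r"^m[_.](?P<id>.+)$",
}


@dataclass
class PosteriorTrace:
    """Retained MCMC samples with column roles.

    ``roles`` maps column name → (role, id) with role ∈ {theta, tau, m};
    unclassified columns (sample index, likelihoods) are kept but ignored by
    downstream operations.  ``chain`` holds a per-row chain id so replicate
    runs can be summarised both per chain and pooled.
    """

    samples: pd.DataFrame
    roles: dict[str, tuple[str, str]]
    chain: np.ndarray
    burnin_fraction: float = 0.0
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("a trace needs at least 2 retained samples")
        for col, (role, _) in self.roles.items():
            if role in ("theta", "tau", "m") and (self.samples[col] < 0).any():
                raise ValueError(f"column {col!r}: negative {role} values")

    def column_for(self, role: str, ident: str) -> str:
        for col, (r, i) in self.roles.items():
            if r == role and i == ident:
                return col
        raise KeyError(f"no {role} column for {ident!r}")

    def values(self, role: str, ident: str) -> np.ndarray:
        return self.samples[self.column_for(role, ident)].to_numpy(float)

    def columns(self, role: str) -> list[str]:
        return [c for c, (r, _) in self.roles.items() if r == role]


def _classify(columns, patterns) -> dict[str, tuple[str, str]]:
    roles: dict[str, tuple[str, str]] = {}
    for col in columns:
        for role, pat in patterns.items():
            mt = re.match(pat, col)
            if mt:
                roles[col] = (role, mt.group("id"))
                break
    return roles


def read_trace(
    paths,
    burnin_fraction: float = 0.10,
    role_patterns: dict[str, str] | None = None,
) -> PosteriorTrace:
    """Read one or more tab-separated trace files.

    Burn-in (default 10%) is applied per chain before concatenation: the
    first ⌈burnin_fraction × rows⌉ rows of each file are discarded.  Chain
    ids (file order) are preserved in the result.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    if not (0 <= burnin_fraction < 1):
        raise ValueError("burnin_fraction must be in [0, 1)")
    patterns = role_patterns or DEFAULT_ROLE_PATTERNS

    frames = []
    chain_ids = []
    for chain, path in enumerate(paths):
        df = pd.read_csv(path, sep="\t")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric cells in trace body: {exc}") from exc
        n_drop = math.ceil(burnin_fraction * len(df))
        kept = df.iloc[n_drop:]
        if len(kept) == 0:
            raise ValueError(f"{path}: zero retained rows after burn-in")
        frames.append(kept)
        chain_ids.append(np.full(len(kept), chain))
    samples = pd.concat(frames, ignore_index=True)
    roles = _classify(samples.columns, patterns)
    if not roles:
        raise ValueError("no trace column classified as theta/tau/m")
    return PosteriorTrace(
        samples=samples,
        roles=roles,
        chain=np.concatenate(chain_ids),
        burnin_fraction=burnin_fraction,
        source=[str(p) for p in paths],
    )


def write_trace(trace: PosteriorTrace, path) -> None:
    """Write retained samples back out in the tab-separated trace dialect."""
    trace.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval and convergence summaries


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing at least ``mass`` of the samples.

    Scans all windows of k = ⌈mass·n⌉ consecutive sorted values and returns
    the narrowest; ties break to the lowest-start window.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("samples must be finite")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    k = math.ceil(mass * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return (float(x[i]), float(x[i + k - 1]))


def effective_sample_size(samples) -> float:
    """ESS by initial-positive-sequence autocorrelation truncation.

    ESS = n / (1 + 2 Σ_k ρ̂_k), summing sample autocorrelations until the
    first non-positive estimate.  Deterministic; capped at n (an
    anticorrelated chain is reported as at most n); a constant series has no
    defined autocorrelation and is reported as n with a warning.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        warnings.warn("constant series: ESS undefined, reporting n", stacklevel=2)
        return float(n)
    # FFT autocovariance
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(min(n / (1 + 2 * s), n))


@dataclass(frozen=True)
class IntervalSummary:
    """Posterior summary: mean, HPD bounds, interval mass and ESS."""

    mean: float
    lower: float
    upper: float
    mass: float = 0.95
    ess: float = float("nan")
    replicate_mean: float | None = None  # mean of per-chain means, if chains known

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("HPD lower must not exceed upper")
        if not (0 < self.mass < 1):
            raise ValueError("mass must be in (0, 1)")


def summarize_posterior(
    values, mass: float = 0.95, chain: np.ndarray | None = None
) -> IntervalSummary:
    """Mean, HPD and ESS of a posterior sample.

    With chain ids, the replicate-chain convention is also reported: the
    mean of per-chain means (samples remain pooled for the HPD).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    lo, hi = hpd_interval(x, mass)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant series: ESS := n
            ess = effective_sample_size(x)
    except ValueError:
        ess = float("nan")
    rep_mean = None
    if chain is not None:
        rep_mean = float(
            np.mean([x[chain == c].mean() for c in np.unique(chain)])
        )
    return IntervalSummary(
        mean=float(x.mean()), lower=lo, upper=hi, mass=mass, ess=ess,
        replicate_mean=rep_mean,
    )


# ---------------------------------------------------------------------------
# conversion to absolute units


def draw_calibrations(
    scale: ScaleConfig, n_draws: int, rng: np.random.Generator | int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired (g, μ) calibration samples.

    g ~ exp(Normal(g_meanlog, g_sdlog)) years; μ ~ Gamma with the configured
    mean and standard deviation (shape = (mean/sd)², scale = sd²/mean).
    Fixed-value mode returns constant arrays without consuming randomness.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if scale.fixed_g is not None:
        g = np.full(n_draws, scale.fixed_g)
    else:
        g = rng.lognormal(scale.g_meanlog, scale.g_sdlog, size=n_draws)
    if scale.fixed_mu is not None:
        mu = np.full(n_draws, scale.fixed_mu)
    else:
        mu = rng.gamma(scale.gamma_shape, scale.gamma_scale, size=n_draws)
    return g, mu


def convert_sample(
    theta: float, tau: float, m: float, theta_target: float, g: float, mu: float
) -> dict[str, float]:
    """Convert one mutation-scaled sample to absolute units.

    N_e = θ/(4μ) individuals; T = (τ/μ)·g years; 2Nm = m·θ_target/2 where
    θ_target belongs to the receiving (forward-time target) population —
    2Nm is free of μ and g by construction.
    """
    if mu <= 0 or g <= 0:
        raise ValueError("μ and g must be strictly positive")
    if min(theta, tau, m, theta_target) < 0:
        raise ValueError("θ, τ, m must be non-negative")
    return {
        "Ne": theta / (4.0 * mu),
        "T_years": (tau / mu) * g,
        "2Nm": m * theta_target / 2.0,
    }


@dataclass
class ConvertedPosterior:
    """Per-sample absolute quantities after Monte-Carlo calibration.

    Columns: ``g``, ``mu``, ``Ne_<branch>``, ``T_<node>``, ``2Nm_<band>``;
    same row count (and chain ids) as the source trace.
    """

    samples: pd.DataFrame
    chain: np.ndarray
    scale: ScaleConfig

    def summarize(self, mass: float = 0.95) -> dict[str, IntervalSummary]:
        return {
            col: summarize_posterior(self.samples[col], mass=mass, chain=self.chain)
            for col in self.samples.columns
        }


def monte_carlo_convert(
    trace: PosteriorTrace,
    model: DemographyModel,
    scale: ScaleConfig,
    seed: int | np.random.Generator = 0,
) -> ConvertedPosterior:
    """Convert a whole trace, one (g, μ) draw per retained sample.

    θ columns become N_e, τ columns divergence times in years, and m columns
    population migration rates 2Nm using the same row's θ of the receiving
    population.  All trace columns must resolve against the model.
    """
    n = len(trace.samples)
    g, mu = draw_calibrations(scale, n, seed)
    out: dict[str, np.ndarray] = {"g": g, "mu": mu}
    for col in trace.columns("theta"):
        ident = trace.roles[col][1]
        if ident not in model.names:
            raise KeyError(f"θ column {col!r} does not resolve against the model")
        out[f"Ne_{ident}"] = trace.samples[col].to_numpy(float) / (4.0 * mu)
    for col in trace.columns("tau"):
        ident = trace.roles[col][1]
        if ident not in model.tau:
            raise KeyError(f"τ column {col!r} does not resolve against the model")
        out[f"T_{ident}"] = trace.samples[col].to_numpy(float) / mu * g
    for col in trace.columns("m"):
        ident = trace.roles[col][1]
        try:
            source, target = ident.split("->")
        except ValueError as exc:
            raise KeyError(f"m column {col!r}: band id must be 'source->target'") from exc
        theta_col = trace.column_for("theta", target)
        out[f"2Nm_{ident}"] = (
            trace.samples[col].to_numpy(float)
            * trace.samples[theta_col].to_numpy(float)
            / 2.0
        )
    return ConvertedPosterior(
        samples=pd.DataFrame(out), chain=trace.chain, scale=scale
    )


# ---------------------------------------------------------------------------
# migration-band screening


def screen_migration_bands(
    trace: PosteriorTrace,
    bands: list[str] | None = None,
    mass: float = 0.95,
) -> dict[str, dict]:
    """Retain bands whose HPD interval of m is bounded away from zero.

    A band is retained iff the lower bound of the ``mass`` HPD interval of
    its m samples is strictly positive (at the precision carried by the
    trace file; no epsilon).  Returns per-band decisions with intervals.
    """
    if bands is None:
        bands = [trace.roles[c][1] for c in trace.columns("m")]
    report: dict[str, dict] = {}
    for band in bands:
        values = trace.values("m", band)  # KeyError if the column is missing
        lo, hi = hpd_interval(values, mass)
        report[band] = {
            "retained": bool(lo > 0),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "mean": float(values.mean()),
            "mass": mass,
        }
    return report
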