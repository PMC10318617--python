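"""Packaged example demography and synthetic posterior traces.

The example demography mirrors the published isolation-with-migration model
for *Microcebus gerpi* and its sister species: seven tip lineages — the
northern populations Sahamamy and Andobo, the southern populations
VohiposaSahafina (two sites merged for lack of reciprocal monophyly),
Ambodisakoana and Antanambao, and the outgroup species *M. jollyae* and
*M. marohita* — on a fixed topology, with 12 directed migration bands
(6 bidirectional pairs) in the migration variant.

θ and τ values are synthetic: where the study prints converted quantities
(divergence times in ka, N_e in individuals, 2Nm), the mutation-scaled
values here are back-converted with the central calibrations g = 3.5 y and
μ = 1.236e-8; parameters the study does not print (ancestral θ, the southern
clade's internal split, θ of most tips) are plausible round values chosen
once.  The synthetic trace generator produces autocorrelated lognormal
wiggle around these values so that HPD/ESS machinery has realistic input;
it emulates an MCMC posterior, not the study's actual chains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import DemographyModel, MigrationBand

__all__ = [
    "example_demography",
    "synthetic_trace",
    "TAU_SCALE",
]

# years → τ with the central calibrations (μ = 1.236e-8, g = 3.5 y)
TAU_SCALE = 1.236e-8 / 3.5

_NE = {  # individuals; printed values where available, synthetic otherwise
    "Sahamamy": 9000.0,
    "Andobo": 3600.0,  # printed
    "VohiposaSahafina": 14900.0,  # printed
    "Ambodisakoana": 7000.0,
    "Antanambao": 8000.0,
    "jollyae": 28500.0,
    "marohita": 28500.0,
    "north": 10000.0,
    "southwest": 10000.0,
    "south": 12000.0,
    "gerpi": 15000.0,
    "sisters": 20000.0,
    "root": 25000.0,
}

_T_YEARS = {  # divergence times; printed where available (migration model)
    "north": 43_000.0,  # Sahamamy–Andobo split
    "southwest": 41_000.0,  # VohiposaSahafina–Ambodisakoana split
    "south": 120_000.0,  # Antanambao vs southwest clade (synthetic)
    "gerpi": 254_000.0,  # north–south split across the Rianila
    "sisters": 272_000.0,  # marohita–jollyae split
    "root": 453_000.0,  # M. gerpi vs sister taxa
}

_T_YEARS_NOMIG = dict(_T_YEARS, north=3_100.0)  # printed no-migration value

_PARENT = {
    "Sahamamy": "north",
    "Andobo": "north",
    "VohiposaSahafina": "southwest",
    "Ambodisakoana": "southwest",
    "southwest": "south",
    "Antanambao": "south",
    "north": "gerpi",
    "south": "gerpi",
    "jollyae": "sisters",
    "marohita": "sisters",
    "gerpi": "root",
    "sisters": "root",
}

# 2Nm per directed band; printed values for three bands, synthetic otherwise
_BAND_2NM = {
    ("Sahamamy", "Andobo"): 1.15,  # printed
    ("Andobo", "Sahamamy"): 0.45,
    ("Ambodisakoana", "Antanambao"): 0.11,  # printed
    ("Antanambao", "Ambodisakoana"): 0.30,  # printed
    ("VohiposaSahafina", "Ambodisakoana"): 0.08,
    ("Ambodisakoana", "VohiposaSahafina"): 0.06,
    ("VohiposaSahafina", "Antanambao"): 0.05,
    ("Antanambao", "VohiposaSahafina"): 0.04,
    ("Sahamamy", "VohiposaSahafina"): 0.02,
    ("VohiposaSahafina", "Sahamamy"): 0.02,
    ("jollyae", "marohita"): 0.03,
    ("marohita", "jollyae"): 0.02,
}


def example_demography(migration: bool = True) -> DemographyModel:
    """The packaged seven-tip mouse-lemur demography.

    With ``migration=True`` (default) the model carries the 12 directed
    bands of the final migration model; with ``migration=False`` it has no
    bands and uses the no-migration divergence times where those differ
    (the Sahamamy–Andobo split collapses to ~3.1 ka).
    """
    mu = 1.236e-8
    theta = {pop: 4.0 * ne * mu for pop, ne in _NE.items()}
    t_years = _T_YEARS if migration else _T_YEARS_NOMIG
    tau = {node: t * TAU_SCALE for node, t in t_years.items()}
    bands = []
    if migration:
        for (src, tgt), nm2 in _BAND_2NM.items():
            pair = "~".join(sorted((src, tgt)))
            m = 2.0 * nm2 / theta[tgt]  # 2Nm = m·θ_target/2
            bands.append(MigrationBand(source=src, target=tgt, rate=m, pair_id=pair))
    return DemographyModel(
        names={pop: pop for pop in _NE},
        parent=dict(_PARENT),
        theta=theta,
        tau=tau,
        bands=bands,
    )


def synthetic_trace(
    model: DemographyModel,
    n_samples: int = 2500,
    n_chains: int = 1,
    seed: int = 0,
    rel_sd: float = 0.03,
    autocorr: float = 0.6,
) -> list[pd.DataFrame]:
    """Generate synthetic MCMC-style trace frames around a model's values.

    Each θ/τ/m column is value·exp(σ·z) with z a stationary AR(1) normal
    series (lag-1 correlation ``autocorr``, marginal sd 1) and σ = rel_sd,
    giving positive, autocorrelated samples whose posterior mean is ≈ the
    model value.  One frame per chain, in the tab-separated trace dialect's
    column naming (theta_<pop>, tau_<node>, m_<src>-><tgt>).
    """
    if not (0 <= autocorr < 1):
        raise ValueError("autocorr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    columns: dict[str, float] = {}
    for pop in sorted(model.theta):
        columns[f"theta_{pop}"] = model.theta[pop]
    for node in sorted(model.tau):
        columns[f"tau_{node}"] = model.tau[node]
    for band in sorted(model.bands, key=lambda b: b.name):
        columns[f"m_{band.name}"] = band.rate

    frames = []
    innov_sd = np.sqrt(1.0 - autocorr**2)
    for _ in range(n_chains):
        data = {"Sample": np.arange(n_samples, dtype=float)}
        for col, value in columns.items():
            z = np.empty(n_samples)
            z[0] = rng.normal()
            eps = rng.normal(scale=innov_sd, size=n_samples)
            for t in range(1, n_samples):
                z[t] = autocorr * z[t - 1] + eps[t]
            data[col] = value * np.exp(rel_sd * z)
        frames.append(pd.DataFrame(data))
    return frames
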