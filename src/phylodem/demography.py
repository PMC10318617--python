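"""Isolation-with-migration demographic models.

A demography is a rooted binary population tree in mutation-scaled units:
per-branch ``theta`` (θ = 4·N_e·μ, dimensionless per site), per-internal-node
``tau`` (τ, expected substitutions per site per lineage; tips sit at τ = 0),
and a set of directed migration bands, each carrying a mutation-scaled rate
``m`` (per-generation migration probability divided by μ).  Absolute units
(individuals, years, migrants per generation) exist only after calibration —
see :mod:`phylodem.trace_post`.

A population exists on the half-open time interval ``[birth τ, parent τ)``,
where birth τ is 0 for tips and the node's own τ for ancestral populations;
the root extends to +∞.  A migration band is active only on the intersection
of its two endpoint populations' existence intervals.

Bidirectional gene flow is represented as two directed bands sharing a
``pair_id`` so that posterior screening can retain one direction and drop the
other.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "MigrationBand",
    "SampleConfig",
    "ScaleConfig",
    "DemographyModel",
    "load_demography",
    "save_demography",
    "loads_demography",
    "dumps_demography",
    "validate_demography",
    "band_activity_interval",
    "DemographyError",
]


class DemographyError(ValueError):
    """Raised when a demography document is malformed or violates an invariant."""


@dataclass(frozen=True)
class MigrationBand:
    """Directed gene-flow channel, read in forward time (donor → recipient).

    Parameters
    ----------
    source : str
        Forward-time donor population id.
    target : str
        Forward-time recipient population id.
    rate : float
        Mutation-scaled migration rate m ≥ 0 (per-generation probability / μ).
    pair_id : str, optional
        Shared identifier linking the two directions of a bidirectional band.
    """

    source: str
    target: str
    rate: float
    pair_id: str | None = None

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class SampleConfig:
    """Number of sampled diploid individuals per population.

    Haplotype counts are twice the individual counts.
    """

    individuals: Mapping[str, int]

    def __post_init__(self) -> None:
        for pop, n in self.individuals.items():
            if n < 0:
                raise DemographyError(f"negative sample count for {pop!r}")
        if self.total_haplotypes < 2:
            raise DemographyError("at least two haplotypes must be sampled in total")

    @property
    def total_haplotypes(self) -> int:
        return 2 * sum(self.individuals.values())

    def haplotypes(self, pop: str) -> int:
        return 2 * self.individuals.get(pop, 0)


@dataclass(frozen=True)
class ScaleConfig:
    """Calibration distributions used to convert mutation-scaled units.

    Generation time g (years) is lognormal with location ``g_meanlog`` and
    scale ``g_sdlog`` on the log scale; mutation rate μ (per site per
    generation) is gamma, parameterised by its mean and standard deviation.
    Defaults are the grey mouse-lemur-derived calibrations used for
    *Microcebus*: median g = 3.5 y, mean μ = 1.236e-8.

    Setting ``fixed_g`` / ``fixed_mu`` bypasses the draws deterministically.
    """

    g_meanlog: float = math.log(3.5)
    g_sdlog: float = math.log(1.16)
    mu_mean: float = 1.236e-8
    mu_sd: float = 0.107e-8
    n_draws: int = 100_000
    fixed_g: float | None = None
    fixed_mu: float | None = None

    def __post_init__(self) -> None:
        for name in ("g_sdlog", "mu_mean", "mu_sd"):
            if getattr(self, name) <= 0:
                raise DemographyError(f"{name} must be strictly positive")
        if self.n_draws < 1:
            raise DemographyError("n_draws must be >= 1")
        for name in ("fixed_g", "fixed_mu"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DemographyError(f"{name} must be strictly positive")

    @property
    def gamma_shape(self) -> float:
        return (self.mu_mean / self.mu_sd) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.mu_sd**2 / self.mu_mean


@dataclass
class DemographyModel:
    """Rooted binary population tree with θ/τ parameters and migration bands.

    Parameters
    ----------
    names : mapping
        Population id → display name.  Every node (tip or ancestral) is a
        population and carries a θ.
    parent : mapping
        Child id → parent id; the root is the single id that never appears
        as a key.
    theta : mapping
        Branch id → θ (> 0), for every node including the root.
    tau : mapping
        Internal node id → τ (> 0).  Tips implicitly have τ = 0.
    bands : list of MigrationBand
    """

    names: dict[str, str]
    parent: dict[str, str]
    theta: dict[str, float]
    tau: dict[str, float]
    bands: list[MigrationBand] = field(default_factory=list)

    # -- derived structure -------------------------------------------------

    @property
    def populations(self) -> list[str]:
        return sorted(self.names)

    @property
    def root(self) -> str:
        roots = [p for p in self.names if p not in self.parent]
        if len(roots) != 1:
            raise DemographyError(f"tree must have exactly one root, found {roots!r}")
        return roots[0]

    @property
    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {p: [] for p in self.names}
        for child, par in self.parent.items():
            out.setdefault(par, []).append(child)
        for v in out.values():
            v.sort()
        return out

    @property
    def tips(self) -> list[str]:
        ch = self.children
        return sorted(p for p in self.names if not ch[p])

    @property
    def internal_nodes(self) -> list[str]:
        ch = self.children
        return sorted(p for p in self.names if ch[p])

    def birth_time(self, pop: str) -> float:
        """τ at which the population comes into existence (0 for tips)."""
        return self.tau.get(pop, 0.0)

    def existence_interval(self, pop: str) -> tuple[float, float]:
        """Half-open ``[birth τ, parent τ)`` interval; root extends to +inf."""
        if pop not in self.names:
            raise DemographyError(f"unknown population {pop!r}")
        end = self.tau[self.parent[pop]] if pop in self.parent else math.inf
        return (self.birth_time(pop), end)

    def mrca(self, a: str, b: str) -> str:
        """Most recent common ancestor of two populations."""
        for p in (a, b):
            if p not in self.names:
                raise DemographyError(f"unknown population {p!r}")
        ancestors = set()
        node: str | None = a
        while node is not None:
            ancestors.add(node)
            node = self.parent.get(node)
        node = b
        while node is not None:
            if node in ancestors:
                return node
            node = self.parent.get(node)
        raise DemographyError(f"populations {a!r} and {b!r} share no ancestor")

    def content_hash(self) -> str:
        """Stable hash of the canonical document (for provenance manifests)."""
        return hashlib.sha256(dumps_demography(self).encode()).hexdigest()[:16]

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {"id": p, "name": self.names[p]} for p in sorted(self.names)
            ],
            "edges": {c: self.parent[c] for c in sorted(self.parent)},
            "theta": {p: self.theta[p] for p in sorted(self.theta)},
            "tau": {p: self.tau[p] for p in sorted(self.tau)},
            "migration_bands": [
                {
                    "source": b.source,
                    "target": b.target,
                    "rate": b.rate,
                    "pair_id": b.pair_id,
                }
                for b in sorted(self.bands, key=lambda b: (b.source, b.target))
            ],
        }

    def to_newick(self) -> str:
        """Topology with branch lengths = parent τ − child birth τ (τ units)."""

        def fmt(node: str) -> str:
            ch = self.children[node]
            if node in self.parent:
                blen = self.tau[self.parent[node]] - self.birth_time(node)
                suffix = f":{blen:.10g}"
            else:
                suffix = ""
            if not ch:
                return f"{node}{suffix}"
            inner = ",".join(fmt(c) for c in ch)
            return f"({inner}){node}{suffix}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# validation


def validate_demography(model: DemographyModel) -> list[str]:
    """Check all structural invariants; return a list of violation messages.

    An empty list means the model is valid.  Each message names the offending
    node or band and the rule violated.
    """
    v: list[str] = []
    pops = set(model.names)

    for child, par in model.parent.items():
        if child not in pops:
            v.append(f"edge child {child!r}: unknown node reference")
        if par not in pops:
            v.append(f"edge parent {par!r}: unknown node reference")
    roots = [p for p in pops if p not in model.parent]
    if len(roots) != 1:
        v.append(f"tree must have exactly one root, found {sorted(roots)!r}")
        return v
    root = roots[0]

    # connectivity + binarity
    ch = model.children
    seen: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if node in seen:
            v.append(f"node {node!r}: cycle detected")
            return v
        seen.add(node)
        kids = ch.get(node, [])
        if len(kids) not in (0, 2):
            v.append(f"node {node!r}: must have 0 or 2 children, has {len(kids)}")
        stack.extend(kids)
    for p in pops - seen:
        v.append(f"node {p!r}: unreachable from root")

    internal = {p for p in pops if ch.get(p)}
    for p in internal:
        if p not in model.tau:
            v.append(f"node {p!r}: internal node missing τ")
    for p in model.tau:
        if p not in internal:
            v.append(f"node {p!r}: τ given for a tip (tips have τ = 0)")

    for p in pops:
        if p not in model.theta:
            v.append(f"branch {p!r}: missing θ")
        elif not model.theta[p] > 0:
            v.append(f"branch {p!r}: θ > 0 violated (θ = {model.theta[p]!r})")

    for p in internal & set(model.tau):
        tp = model.tau[p]
        if not tp > 0:
            v.append(f"node {p!r}: τ > 0 violated (τ = {tp!r})")
        for c in ch[p]:
            tc = model.tau.get(c, 0.0)
            if not tp > tc:
                v.append(
                    f"node {p!r}: τ(parent) > τ(child) violated "
                    f"(τ = {tp!r} vs child {c!r} at {tc!r})"
                )

    for b in model.bands:
        label = f"band {b.name}"
        if b.source == b.target:
            v.append(f"{label}: source == target")
            continue
        missing = [p for p in (b.source, b.target) if p not in pops]
        if missing:
            v.append(f"{label}: unknown population {missing[0]!r}")
            continue
        if b.rate < 0:
            v.append(f"{label}: m ≥ 0 violated (m = {b.rate!r})")
        try:
            s0, s1 = model.existence_interval(b.source)
            t0, t1 = model.existence_interval(b.target)
        except (DemographyError, KeyError):
            continue
        if min(s1, t1) <= max(s0, t0):
            v.append(f"{label}: non-overlapping existence intervals")
    return v


def band_activity_interval(
    model: DemographyModel, band: MigrationBand
) -> tuple[float, float]:
    """Time interval (τ units) on which a band is active.

    The intersection of the two endpoint populations' existence intervals.
    Raises :class:`DemographyError` if the intersection is empty.
    """
    s0, s1 = model.existence_interval(band.source)
    t0, t1 = model.existence_interval(band.target)
    lo, hi = max(s0, t0), min(s1, t1)
    if hi <= lo:
        raise DemographyError(
            f"band {band.name}: empty intersection of existence intervals "
            f"[{s0:g}, {s1:g}) and [{t0:g}, {t1:g})"
        )
    return (lo, hi)


# ---------------------------------------------------------------------------
# document I/O (canonical JSON dialect)


def _model_from_dict(doc: dict) -> DemographyModel:
    try:
        names = {p["id"]: p.get("name", p["id"]) for p in doc["populations"]}
        parent = dict(doc["edges"])
        theta = {k: float(x) for k, x in doc["theta"].items()}
        tau = {k: float(x) for k, x in doc["tau"].items()}
        bands = [
            MigrationBand(
                source=b["source"],
                target=b["target"],
                rate=float(b["rate"]),
                pair_id=b.get("pair_id"),
            )
            for b in doc.get("migration_bands", [])
        ]
    except (KeyError, TypeError) as exc:
        raise DemographyError(f"malformed demography document: {exc}") from exc
    model = DemographyModel(names=names, parent=parent, theta=theta, tau=tau, bands=bands)
    violations = validate_demography(model)
    if violations:
        raise DemographyError("; ".join(violations))
    return model


def loads_demography(text: str) -> DemographyModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DemographyError(f"demography document does not parse: {exc}") from exc
    return _model_from_dict(doc)


def dumps_demography(model: DemographyModel) -> str:
    """Canonical writer: sorted keys, fixed indentation, trailing newline."""
    return json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n"


def load_demography(path) -> DemographyModel:
    """Read and validate a demography JSON document."""
    with open(path) as fh:
        return loads_demography(fh.read())


def save_demography(model: DemographyModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_demography(model))
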