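"""Population-genetic summary statistics on multilocus datasets.

Joint two-population site-frequency spectra, weighted F_ST (Hudson and
Reynolds-style coancestry estimators, ratio-of-sums across sites), Slatkin's
linearisation F_ST/(1−F_ST), nucleotide diversity π, Watterson's θ̂_W,
between-population divergence d_xy, moment estimators of (θ, τ), individual
genetic distance matrices and the Mantel permutation test for isolation by
distance.

Missing data are handled complete-case per site: a site contributes only
when every individual involved in the computation is genotyped at its locus
(RAD missingness is whole-locus dropout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coalsim import MultilocusDataset

__all__ = [
    "SFS2D",
    "DistanceMatrix",
    "joint_sfs",
    "weighted_fst",
    "slatkin_linearize",
    "diversity_stats",
    "moment_estimates",
    "genetic_distance_matrix",
    "population_distance_matrix",
    "mantel_test",
    "harmonic_number",
    "plot_ibd",
]


def harmonic_number(k: int) -> float:
    """a_k = Σ_{i=1}^{k} 1/i, the Watterson normaliser for k+1 sequences."""
    return float(sum(1.0 / i for i in range(1, k + 1)))


@dataclass
class SFS2D:
    """Joint two-population allele-frequency spectrum.

    ``counts[i, j]`` is the number of sites with derived (or, folded, pooled
    minor) allele count i in population 1 (haploid size n1) and j in
    population 2 (haploid size n2).  Monomorphic sites, when tracked, sit in
    cell (0, 0).
    """

    counts: np.ndarray
    n1: int
    n2: int
    pop1: str
    pop2: str
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("SFS shape must be (n1+1, n2+1)")
        if (self.counts < 0).any():
            raise ValueError("SFS entries must be non-negative")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def fold(self) -> "SFS2D":
        """Fold onto the pooled minor-allele orientation.

        Cells with pooled count above (n1+n2)/2 are reflected to
        (n1−i, n2−j); exact ties keep the derived orientation.
        """
        if self.folded:
            return self
        n1, n2 = self.n1, self.n2
        out = np.zeros_like(self.counts)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                if 2 * (i + j) > n1 + n2:
                    out[n1 - i, n2 - j] += self.counts[i, j]
                else:
                    out[i, j] += self.counts[i, j]
        return SFS2D(out, n1, n2, self.pop1, self.pop2, folded=True)

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# joint SFS {self.pop1} (rows) x {self.pop2} (cols)\n")
            fh.write(f"# n1={self.n1}\tn2={self.n2}\tfolded={self.folded}\n")
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}={v}\n")
            for row in self.counts:
                fh.write("\t".join(str(int(x)) for x in row) + "\n")


def _included_loci(dataset: MultilocusDataset, ind_idx: list[int]) -> list[int]:
    """Loci at which every listed individual is genotyped (complete case)."""
    mask = dataset.missing[ind_idx, :]
    return [l for l in range(dataset.n_loci) if not mask[:, l].any()]


def _hap_rows(dataset: MultilocusDataset, ind_idx: list[int]) -> list[int]:
    rows: list[int] = []
    for i in ind_idx:
        rows.extend(dataset.individuals[i].haplotypes)
    return rows


def joint_sfs(
    dataset: MultilocusDataset,
    pop1: str,
    pop2: str,
    folded: bool = False,
    include_monomorphic: bool = True,
) -> SFS2D:
    """Joint SFS of a population pair from haplotype data.

    Sites with missing data in either population are excluded (with
    whole-locus dropout this removes whole loci).  With
    ``include_monomorphic``, invariant positions of included loci are added
    to cell (0, 0) so that totals equal the number of contributing sites.
    """
    for pop in (pop1, pop2):
        if pop not in dataset.populations:
            raise ValueError(f"unknown population {pop!r}")
    idx1 = dataset.individuals_of(pop1)
    idx2 = dataset.individuals_of(pop2)
    n1, n2 = 2 * len(idx1), 2 * len(idx2)
    rows1 = _hap_rows(dataset, idx1)
    rows2 = _hap_rows(dataset, idx2)
    loci = _included_loci(dataset, idx1 + idx2)
    if not loci:
        raise ValueError(f"no loci with complete data for {pop1!r} vs {pop2!r}")

    counts = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    for l in loci:
        h = dataset.loci[l].haplotypes
        i_counts = h[rows1, :].sum(axis=0)
        j_counts = h[rows2, :].sum(axis=0)
        np.add.at(counts, (i_counts, j_counts), 1)
        if include_monomorphic:
            counts[0, 0] += dataset.loci[l].length - h.shape[1]
    sfs = SFS2D(counts, n1, n2, pop1, pop2, folded=False)
    return sfs.fold() if folded else sfs


def _hudson_terms(p1, p2, n1, n2):
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _reynolds_terms(p1, p2, n1, n2):
    # coancestry (θ) estimator for haploid allele counts: the two-population
    # Weir–Cockerham components without heterozygosity terms, the form the
    # Reynolds et al. (1983) estimator takes for gene-count data
    nbar = (n1 + n2) / 2.0
    nc = 2.0 * n1 * n2 / (n1 + n2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    within = pbar * (1 - pbar) - s2 / 2.0
    a = (nbar / nc) * (s2 - within / (nbar - 1))
    b = (nbar / (nbar - 1)) * within
    return a, a + b


def weighted_fst(sfs: SFS2D, estimator: str = "hudson") -> float:
    """Weighted (ratio-of-sums) F_ST from a joint SFS.

    F_ST = Σ_sites num / Σ_sites den, with per-site numerator/denominator
    from the chosen estimator; sites monomorphic across the pooled pair are
    skipped.  ``hudson`` (default) is the Hudson/Bhatia estimator; ``reynolds``
    the coancestry estimator of the Reynolds–Weir–Cockerham family.
    """
    if estimator not in ("hudson", "reynolds"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n1, n2 = sfs.n1, sfs.n2
    if n1 < 2 or n2 < 2:
        raise ValueError("both populations need n >= 2 haplotypes")
    terms = _hudson_terms if estimator == "hudson" else _reynolds_terms
    num_sum = 0.0
    den_sum = 0.0
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            c = sfs.counts[i, j]
            if c == 0 or i + j == 0 or i + j == n1 + n2:
                continue
            num, den = terms(i / n1, j / n2, n1, n2)
            num_sum += c * num
            den_sum += c * den
    if den_sum == 0:
        raise ValueError("no polymorphic sites: weighted F_ST undefined")
    return num_sum / den_sum


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearised F_ST, F_ST / (1 − F_ST)."""
    if fst >= 1:
        raise ValueError("linearisation requires F_ST < 1")
    return fst / (1.0 - fst)


def diversity_stats(
    dataset: MultilocusDataset,
    pop1: str,
    pop2: str | None = None,
) -> dict[str, float]:
    """Per-site diversity and divergence, averaged over loci by length.

    Returns π (mean pairwise difference per site) and Watterson's θ̂_W for
    ``pop1`` (and ``pop2`` if given), plus d_xy between the pair.  Loci with
    missing individuals are dropped per statistic (complete case); the
    Watterson normaliser uses the per-locus haplotype count.
    """
    out: dict[str, float] = {}

    def within(pop: str) -> tuple[float, float]:
        idx = dataset.individuals_of(pop)
        if not idx:
            raise ValueError(f"unknown or empty population {pop!r}")
        rows = _hap_rows(dataset, idx)
        if len(rows) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 haplotypes")
        loci = _included_loci(dataset, idx)
        if not loci:
            raise ValueError(f"no complete loci for {pop!r}")
        diff_sum = 0.0
        s_sum = 0.0
        len_sum = 0.0
        aw_sum = 0.0
        n = len(rows)
        for l in loci:
            h = dataset.loci[l].haplotypes[rows, :]
            d = h.sum(axis=0)
            # mean pairwise difference at a site with derived count d:
            # d(n-d) / C(n,2)
            diff_sum += float((d * (n - d)).sum()) / (n * (n - 1) / 2)
            s_sum += float((0 < d).sum() - (d == n).sum())
            len_sum += dataset.loci[l].length
            aw_sum += harmonic_number(n - 1) * dataset.loci[l].length
        return diff_sum / len_sum, s_sum / aw_sum

    pi1, tw1 = within(pop1)
    out[f"pi_{pop1}"] = pi1
    out[f"theta_w_{pop1}"] = tw1
    out["pi"] = pi1
    out["theta_w"] = tw1

    if pop2 is not None:
        pi2, tw2 = within(pop2)
        out[f"pi_{pop2}"] = pi2
        out[f"theta_w_{pop2}"] = tw2
        idx1 = dataset.individuals_of(pop1)
        idx2 = dataset.individuals_of(pop2)
        rows1 = _hap_rows(dataset, idx1)
        rows2 = _hap_rows(dataset, idx2)
        loci = _included_loci(dataset, idx1 + idx2)
        if not loci:
            raise ValueError("no complete loci for the pair")
        diff_sum = 0.0
        len_sum = 0.0
        for l in loci:
            h = dataset.loci[l].haplotypes
            d1 = h[rows1, :].sum(axis=0).astype(float)
            d2 = h[rows2, :].sum(axis=0).astype(float)
            k1, k2 = len(rows1), len(rows2)
            # per-site mean between-pop difference: p1(1-p2) + p2(1-p1)
            diff_sum += float(
                (d1 / k1 * (1 - d2 / k2) + d2 / k2 * (1 - d1 / k1)).sum()
            )
            len_sum += dataset.loci[l].length
        out["d_xy"] = diff_sum / len_sum
    return out


def moment_estimates(
    dataset: MultilocusDataset, pop1: str, pop2: str
) -> dict[str, float]:
    """Moment estimators of (θ_1, θ_2, τ) for a population pair.

    θ̂ is Watterson's estimator per population; τ̂ is half the net divergence,
    [d_xy − (π_1 + π_2)/2] / 2, unbiased under isolation with equal θ and
    biased when migration or θ asymmetry is strong.
    """
    stats = diversity_stats(dataset, pop1, pop2)
    tau_hat = (stats["d_xy"] - (stats[f"pi_{pop1}"] + stats[f"pi_{pop2}"]) / 2) / 2
    return {
        f"theta_{pop1}": stats[f"theta_w_{pop1}"],
        f"theta_{pop2}": stats[f"theta_w_{pop2}"],
        "tau": tau_hat,
    }


# ---------------------------------------------------------------------------
# distance matrices and the Mantel test


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    values: np.ndarray
    labels: list[str]
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) entries as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# distance matrix metric={self.metric}\n")
            for k, v in (metadata or {}).items():
                fh.write(f"# {k}={v}\n")
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path, metric: str = "") -> "DistanceMatrix":
        labels: list[str] = []
        rows: list[list[float]] = []
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    if line.startswith("# distance matrix metric="):
                        metric = line.split("=", 1)[1]
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts[1:]
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if header is None or labels != header:
            raise ValueError("malformed distance matrix file")
        return cls(np.array(rows), labels, metric=metric)


def genetic_distance_matrix(
    dataset: MultilocusDataset, metric: str = "allele-sharing"
) -> DistanceMatrix:
    """Pairwise genetic distances between individuals.

    ``allele-sharing``: 1 − (shared alleles / 2·sites) = mean |dosage
    difference| / 2 over pairwise-complete sites.  ``euclidean-dosage``:
    Euclidean distance on 0/1/2 dosages divided by √sites.  Pairs use only
    loci at which both individuals are genotyped.
    """
    if metric not in ("allele-sharing", "euclidean-dosage"):
        raise ValueError(f"unknown metric {metric!r}")
    n_ind = len(dataset.individuals)
    if n_ind < 2:
        raise ValueError("need >= 2 individuals")
    dosages = [dataset.genotype_matrix(l) for l in range(dataset.n_loci)]
    out = np.zeros((n_ind, n_ind))
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            acc = 0.0
            n_sites = 0
            for l in range(dataset.n_loci):
                if dataset.missing[i, l] or dataset.missing[j, l]:
                    continue
                di = dosages[l][i, :].astype(float)
                dj = dosages[l][j, :].astype(float)
                n_sites += dosages[l].shape[1]
                if metric == "allele-sharing":
                    acc += float(np.abs(di - dj).sum())
                else:
                    acc += float(((di - dj) ** 2).sum())
            if n_sites == 0:
                raise ValueError(
                    f"individuals {dataset.individuals[i].id!r} and "
                    f"{dataset.individuals[j].id!r} share no genotyped sites"
                )
            if metric == "allele-sharing":
                out[i, j] = out[j, i] = acc / (2.0 * n_sites)
            else:
                out[i, j] = out[j, i] = math.sqrt(acc) / math.sqrt(n_sites)
    return DistanceMatrix(out, [ind.id for ind in dataset.individuals], metric=metric)


def population_distance_matrix(
    dataset: MultilocusDataset, individual_dm: DistanceMatrix
) -> DistanceMatrix:
    """Population-level matrix: mean over cross-population individual pairs."""
    pops = dataset.populations
    idx = {p: dataset.individuals_of(p) for p in pops}
    ids = [ind.id for ind in dataset.individuals]
    pos = {lab: k for k, lab in enumerate(individual_dm.labels)}
    out = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            vals = [
                individual_dm.values[pos[ids[i]], pos[ids[j]]]
                for i in idx[pops[a]]
                for j in idx[pops[b]]
            ]
            out[a, b] = out[b, a] = float(np.mean(vals))
    return DistanceMatrix(out, pops, metric=f"mean-{individual_dm.metric}")


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Mantel permutation test of matrix correlation.

    r is the Pearson correlation of the off-diagonal triangles; the null is
    generated by jointly permuting rows and columns of the second matrix.
    The one-tailed ("greater") p-value uses the +1 ranking rule:
    p = (1 + #{r_perm ≥ r_obs}) / (1 + n_permutations).
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    v1 = d1.condensed()
    v2 = d2.condensed()
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero off-diagonal variance: r undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z1 = (v1 - v1.mean()) / v1.std()

    def corr_with(mat: np.ndarray) -> float:
        iu = np.triu_indices(n, k=1)
        v = mat[iu]
        s = v.std()
        if s == 0:
            return 0.0
        return float(np.mean(z1 * (v - v.mean()) / s))

    r_obs = corr_with(d2.values)
    count = 0
    m2 = d2.values
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if corr_with(m2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return {
        "r": r_obs,
        "p": p,
        "n_permutations": n_permutations,
        "tail": "greater",
    }


def plot_ibd(
    linearized_fst: DistanceMatrix,
    geographic_km: DistanceMatrix,
    path,
) -> None:
    """Isolation-by-distance scatter: F_ST/(1−F_ST) against log10 km.

    A plot utility only — no regression line is fitted or reported.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if linearized_fst.labels != geographic_km.labels:
        raise ValueError("distance matrices must share labels and order")
    x = np.log10(geographic_km.condensed())
    y = linearized_fst.condensed()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, s=25, color="#1f6e8c", edgecolor="black", linewidth=0.4)
    ax.set_xlabel("geographic distance (log10 km)")
    ax.set_ylabel(r"$F_{ST}\,/\,(1-F_{ST})$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
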