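"""Structured-coalescent simulator with divergence and directional migration.

Simulates genealogies backward in time under a :class:`DemographyModel`:
within a population carrying parameter θ, each pair of lineages coalesces at
rate 2/θ per unit τ (k lineages → total rate k(k−1)/θ); for each directed
band source → target (read in forward time), every lineage currently in the
target population jumps to the source at rate m; at each internal node's τ
the lineages of the two daughter populations relabel instantaneously to the
ancestral population.  Mutations are dropped on the resulting genealogy under
the infinite-sites model: a branch of length b (τ units) on a locus of ℓ bp
receives Poisson(b·ℓ) mutations, each creating a new biallelic segregating
site carried by all leaves below the branch.

Loci are independent and non-recombining — the RAD-locus scale.  Haplotypes
are paired into diploid individuals within populations, and an optional
individual × locus dropout mask emulates whole-locus RAD missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import (
    DemographyModel,
    MigrationBand,
    SampleConfig,
    band_activity_interval,
    validate_demography,
)

__all__ = [
    "Genealogy",
    "Locus",
    "Individual",
    "MultilocusDataset",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "export_vcf",
    "import_vcf",
]


@dataclass
class Genealogy:
    """A realised coalescent tree over sampled haplotypes.

    Nodes 0..n−1 are leaves at time 0; internal nodes are appended in order
    of creation.  ``parent[i] == -1`` marks the root.  Times are in τ units.
    ``migrations`` records (node id of the migrating lineage, band name,
    time) for every backward-time migration event.
    """

    n_leaves: int
    node_time: np.ndarray
    parent: np.ndarray
    leaf_population: list[str]
    migrations: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_time)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.node_time[p] - self.node_time[node])

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf ids descending from ``node`` (the node itself if a leaf)."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        out = []
        stack = [node]
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                out.append(u)
            stack.extend(children[u])
        return np.array(sorted(out), dtype=np.int64)

    def tmrca(self) -> float:
        return float(self.node_time[self.root])


def _require_valid(model: DemographyModel) -> None:
    violations = validate_demography(model)
    if violations:
        raise ValueError("invalid demography: " + "; ".join(violations))


def simulate_genealogy(
    model: DemographyModel,
    samples: SampleConfig | dict[str, int],
    rng: np.random.Generator | int,
) -> Genealogy:
    """Simulate one genealogy under the structured coalescent with migration.

    ``samples`` is a :class:`SampleConfig` (diploid individuals per
    population) or, for low-level use, a plain mapping of population →
    haplotype count.  Event scheduling races exponential clocks among all
    active event classes between consecutive τ breakpoints (the
    internal-node times); at each breakpoint, daughter lineages relabel to
    the ancestral population and all rates are rebuilt.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    _require_valid(model)

    if isinstance(samples, SampleConfig):
        hap_counts = {p: samples.haplotypes(p) for p in samples.individuals}
    else:
        hap_counts = dict(samples)
    # leaves grouped by population, populations in sorted order
    leaf_population: list[str] = []
    for pop in sorted(hap_counts):
        if pop not in model.names:
            raise ValueError(f"sampled population {pop!r} not in demography")
        leaf_population.extend([pop] * hap_counts[pop])
    n = len(leaf_population)
    if n < 2:
        raise ValueError("need at least two haplotypes in total")

    node_time = list(np.zeros(n))
    parent = list(np.full(n, -1, dtype=np.int64))
    migrations: list[tuple[int, str, float]] = []
    # lineage -> current population
    lineages: dict[int, str] = dict(enumerate(leaf_population))
    next_id = n

    band_intervals = [(b, band_activity_interval(model, b)) for b in model.bands]
    breakpoints = sorted(set(model.tau.values()))
    node_at: dict[float, list[str]] = {}
    for node, t in model.tau.items():
        node_at.setdefault(t, []).append(node)
    children = model.children

    t = 0.0
    epoch_ends = breakpoints + [math.inf]
    for t_end in epoch_ends:
        if t_end < t:
            continue
        while len(lineages) > 1:
            # per-population lineage lists
            by_pop: dict[str, list[int]] = {}
            for lid, pop in lineages.items():
                by_pop.setdefault(pop, []).append(lid)
            events: list[tuple[float, str, object]] = []  # (rate, kind, payload)
            for pop, lids in by_pop.items():
                k = len(lids)
                if k >= 2:
                    events.append((k * (k - 1) / model.theta[pop], "coal", pop))
            for band, (a0, a1) in band_intervals:
                if band.rate <= 0 or not (a0 <= t < a1):
                    continue
                k = len(by_pop.get(band.target, ()))
                if k:
                    events.append((band.rate * k, "mig", band))
            total = sum(r for r, _, _ in events)
            if total == 0:
                t = t_end
                break
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_end:
                t = t_end
                break
            t += wait
            # pick the event class; coalescences sort before migrations on
            # (impossible) exact rate ties via listing order
            u = rng.uniform(0, total)
            acc = 0.0
            for rate, kind, payload in events:
                acc += rate
                if u < acc:
                    break
            if kind == "coal":
                pop = payload  # type: ignore[assignment]
                lids = by_pop[pop]
                i, j = rng.choice(len(lids), size=2, replace=False)
                a, b = lids[i], lids[j]
                node_time.append(t)
                parent.append(-1)
                parent[a] = next_id
                parent[b] = next_id
                lineages[next_id] = pop
                del lineages[a], lineages[b]
                next_id += 1
            else:
                band = payload  # type: ignore[assignment]
                lids = by_pop[band.target]
                moved = lids[rng.integers(len(lids))]
                lineages[moved] = band.source
                migrations.append((moved, band.name, t))
        if len(lineages) <= 1:
            break
        if t_end is not math.inf:
            # relabel daughters of every node whose τ equals this breakpoint
            for node in node_at.get(t_end, ()):
                daughters = set(children[node])
                for lid, pop in list(lineages.items()):
                    if pop in daughters:
                        lineages[lid] = node
    if len(lineages) > 1:  # pragma: no cover - root epoch always coalesces
        raise RuntimeError("simulation ended with more than one lineage")

    return Genealogy(
        n_leaves=n,
        node_time=np.asarray(node_time, dtype=float),
        parent=np.asarray(parent, dtype=np.int64),
        leaf_population=leaf_population,
        migrations=migrations,
    )


def drop_mutations(
    genealogy: Genealogy,
    locus_length: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations on a genealogy.

    Returns ``(matrix, positions)``: a haplotype × segregating-site 0/1
    matrix (derived = 1) and the 1-based site positions, sorted.  Each branch
    of length b receives Poisson(b × locus_length) mutations.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")

    n = genealogy.n_leaves
    branch_nodes = [i for i in range(genealogy.n_nodes) if genealogy.parent[i] >= 0]
    lengths = np.array([genealogy.branch_length(i) for i in branch_nodes])
    counts = rng.poisson(lengths * locus_length)
    total = int(counts.sum())
    if total == 0:
        return np.zeros((n, 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)

    # unique positions; if mutations outnumber sites, extend past the locus
    # (infinite-sites semantics trump physical length in this corner)
    if total <= locus_length:
        positions = rng.choice(locus_length, size=total, replace=False) + 1
    else:
        positions = np.arange(total) + 1
    order = rng.permutation(total)  # random branch ↔ position assignment
    matrix = np.zeros((n, total), dtype=np.uint8)
    k = 0
    for node, c in zip(branch_nodes, counts):
        if c == 0:
            continue
        leaves = genealogy.leaves_below(node)
        for _ in range(c):
            matrix[leaves, order[k]] = 1
            k += 1
    sort = np.argsort(positions)
    return matrix[:, sort], positions[sort]


@dataclass
class Locus:
    """One independent non-recombining locus."""

    length: int
    haplotypes: np.ndarray  # (n_haplotypes, n_sites) uint8, derived = 1
    positions: np.ndarray  # 1-based within the locus

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    haplotypes: tuple[int, int]  # row indices into each locus matrix


@dataclass
class MultilocusDataset:
    """RAD-like multilocus genotype data with individual metadata.

    ``missing[i, l]`` is True when individual i was not genotyped at locus l
    (whole-locus dropout).  ``provenance`` records the seed and demography
    hash for simulated data.
    """

    loci: list[Locus]
    individuals: list[Individual]
    missing: np.ndarray  # (n_individuals, n_loci) bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        return sorted({ind.population for ind in self.individuals})

    def individuals_of(self, pop: str) -> list[int]:
        return [i for i, ind in enumerate(self.individuals) if ind.population == pop]

    def genotype_matrix(self, locus_index: int) -> np.ndarray:
        """Dosage matrix (n_individuals × n_sites), −1 for missing."""
        locus = self.loci[locus_index]
        out = np.zeros((len(self.individuals), locus.n_sites), dtype=np.int8)
        for i, ind in enumerate(self.individuals):
            if self.missing[i, locus_index]:
                out[i, :] = -1
            else:
                a, b = ind.haplotypes
                out[i, :] = locus.haplotypes[a, :] + locus.haplotypes[b, :]
        return out


def simulate_dataset(
    model: DemographyModel,
    samples: SampleConfig,
    n_loci: int,
    locus_length: int = 649,
    missingness_rate: float = 0.0,
    seed: int = 0,
) -> MultilocusDataset:
    """Simulate an independent-locus RAD-like dataset.

    Defaults emulate the study design this package targets: loci of ~649 bp
    and two diploid individuals per population.  Fully reproducible from
    ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0 <= missingness_rate < 1):
        raise ValueError("missingness_rate must be in [0, 1)")
    _require_valid(model)

    ss = np.random.SeedSequence(seed)
    rng_pair, rng_mask, rng_loci = [np.random.default_rng(s) for s in ss.spawn(3)]

    # diploid individuals: haplotypes are grouped by population in sorted
    # order; pairing within a population is a seeded permutation
    individuals: list[Individual] = []
    offset = 0
    for pop in sorted(samples.individuals):
        n_ind = samples.individuals[pop]
        haps = offset + rng_pair.permutation(2 * n_ind)
        for k in range(n_ind):
            individuals.append(
                Individual(
                    id=f"{pop}_{k}",
                    population=pop,
                    haplotypes=(int(haps[2 * k]), int(haps[2 * k + 1])),
                )
            )
        offset += 2 * n_ind

    loci: list[Locus] = []
    locus_seeds = rng_loci.integers(0, 2**31 - 1, size=2 * n_loci)
    for i in range(n_loci):
        gen = simulate_genealogy(model, samples, int(locus_seeds[2 * i]))
        matrix, positions = drop_mutations(gen, locus_length, int(locus_seeds[2 * i + 1]))
        loci.append(Locus(length=locus_length, haplotypes=matrix, positions=positions))

    missing = rng_mask.uniform(size=(len(individuals), n_loci)) < missingness_rate
    return MultilocusDataset(
        loci=loci,
        individuals=individuals,
        missing=missing,
        provenance={"seed": seed, "demography": model.content_hash()},
    )


# ---------------------------------------------------------------------------
# VCF interchange (minimal 4.2 dialect)


def export_vcf(dataset: MultilocusDataset, path) -> None:
    """Write the dataset as minimal VCF 4.2.

    One pseudo-contig per locus, biallelic SNPs with REF = ancestral ``A``
    and ALT = derived ``T``, unphased diploid genotypes, ``./.`` for masked
    (individual, locus) entries.  Genotypes are written allele-sorted, so
    haplotype phase is not preserved; dosage matrices round-trip exactly.
    """
    if not dataset.loci:
        raise ValueError("empty dataset")
    sample_ids = [ind.id for ind in dataset.individuals]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phylodem\n")
        for l, locus in enumerate(dataset.loci):
            length = max(locus.length, int(locus.positions.max()) if locus.n_sites else 1)
            fh.write(f"##contig=<ID=locus_{l:06d},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for l, locus in enumerate(dataset.loci):
            geno = dataset.genotype_matrix(l)
            for s in range(locus.n_sites):
                cells = []
                for i in range(len(sample_ids)):
                    d = geno[i, s]
                    cells.append("./." if d < 0 else ["0/0", "0/1", "1/1"][d])
                fh.write(
                    f"locus_{l:06d}\t{locus.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(cells)
                    + "\n"
                )


def import_vcf(path, population_map: dict[str, str] | None = None) -> MultilocusDataset:
    """Read a minimal VCF back into a :class:`MultilocusDataset`.

    Each contig becomes a locus.  Unphased genotypes are split into two
    pseudo-haplotypes in allele-sorted order (phase is arbitrary for
    heterozygotes); all dosage-based statistics are unaffected.

    Parameters
    ----------
    population_map : dict, optional
        Sample id → population id.  When omitted, the prefix of the sample id
        before the last ``_`` is used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if population_map is None:
        population_map = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    contig_lengths = {c: int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)}
    by_contig: dict[str, list[tuple[int, np.ndarray]]] = {c: [] for c in vcf.seqnames}
    for rec in vcf:
        gts = rec.genotype.array()[:, :2]  # (n_samples, 2), -1 missing
        by_contig.setdefault(rec.CHROM, []).append((rec.POS, gts.copy()))
    vcf.close()

    individuals = [
        Individual(
            id=s,
            population=population_map[s],
            haplotypes=(2 * i, 2 * i + 1),
        )
        for i, s in enumerate(sample_ids)
    ]
    n_ind = len(individuals)
    contigs = sorted(by_contig)
    loci: list[Locus] = []
    missing = np.zeros((n_ind, len(contigs)), dtype=bool)
    for l, contig in enumerate(contigs):
        records = sorted(by_contig[contig])
        positions = np.array([p for p, _ in records], dtype=np.int64)
        matrix = np.zeros((2 * n_ind, len(records)), dtype=np.uint8)
        for s, (_, gts) in enumerate(records):
            for i in range(n_ind):
                a, b = sorted(gts[i])
                if a < 0:
                    missing[i, l] = True
                else:
                    matrix[2 * i, s] = a
                    matrix[2 * i + 1, s] = b
        loci.append(
            Locus(
                length=contig_lengths.get(contig, int(positions.max()) if len(positions) else 1),
                haplotypes=matrix,
                positions=positions,
            )
        )
    return MultilocusDataset(loci=loci, individuals=individuals, missing=missing)
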