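"""Deterministic simulator for every pipeline input, with ground truth retained.

All randomness flows from a single seed.  Each public ``simulate_*`` function
accepts either a seed or a ``numpy`` Generator; the same seed always yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AssemblyGap,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    SVRecord,
    Transcript,
    write_bed,
    write_fasta,
    write_gene_gff3,
    write_repeat_table,
    write_sv_vcf,
)

__all__ = [
    "LengthMixture",
    "RepeatFamilySpec",
    "SVSpec",
    "OrthogroupSpec",
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedSVPanel",
    "SimulatedOrthogroups",
    "simulate_genome",
    "simulate_kmer_histogram",
    "simulate_sv_population",
    "simulate_orthogroups",
]

SV_FAIL_RULES = ("max_length", "min_pe", "imprecise", "mapq", "filter")


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class LengthMixture:
    """Mixture of log-normal components: (weight, mean_bp, sd_bp) per component."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        total = sum(w for w, _, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")

    def sample(self, rng: np.random.Generator, n: int, min_len: int = 50) -> np.ndarray:
        weights = np.array([w for w, _, _ in self.components])
        choice = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, (_, mean, sd) in enumerate(self.components):
            mask = choice == i
            k = int(mask.sum())
            if k == 0:
                continue
            # parameterize the log-normal by its arithmetic mean/sd
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            out[mask] = rng.lognormal(mu, np.sqrt(sigma2), size=k)
        return np.maximum(min_len, out.round().astype(int))


# Bimodal defaults mirroring LTR family length peaks near (3, 13) kb and (3, 8) kb.
COPIA_MIXTURE = LengthMixture(((0.5, 3000.0, 800.0), (0.5, 13000.0, 2000.0)))
GYPSY_MIXTURE = LengthMixture(((0.5, 3000.0, 800.0), (0.5, 8000.0, 1500.0)))


@dataclass(frozen=True)
class RepeatFamilySpec:
    label: str  # "class/family" composite
    count: int
    lengths: LengthMixture
    genic_bias: float = 0.0  # probability of forcing placement inside a gene span


@dataclass(frozen=True)
class SVSpec:
    """Per-type SV counts plus deliberate single-rule violators."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"DEL": 30, "DUP": 30, "INV": 15}
    )
    fail_counts: dict[str, int] = field(
        default_factory=lambda: {rule: 2 for rule in SV_FAIL_RULES}
    )
    del_lengths: LengthMixture = GYPSY_MIXTURE
    other_lengths: LengthMixture = LengthMixture(((1.0, 2000.0, 1500.0),))
    af_alpha: float = 0.6
    af_beta: float = 6.0
    fixed_af: float | None = None  # override the Beta draw (boundary tests)


@dataclass(frozen=True)
class OrthogroupSpec:
    n_orthogroups: int = 200
    species: tuple[str, ...] = ("focal", "spA", "spB", "spC")
    focal_species: str = "focal"
    nodes: tuple[str, ...] = ("N0", "N1", "N2", "N3")
    planted_node: str = "N2"
    planted_events: int = 40
    background_events_per_node: int = 20
    low_support_fraction: float = 0.2
    n_terms: int = 20
    enriched_term: str = "T001"
    term_base_rate: float = 0.1
    enrichment_effect: float = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 300_000), ("chr2", 200_000))
    background_gc: float = 0.46
    gap_count: int = 35
    gap_length: int = 100
    # scaled-down footprints so the default 500 kb genome stays placeable at
    # a realistic (~30%) masked fraction; SV length draws use the full-size
    # bimodal mixtures instead
    repeat_families: tuple[RepeatFamilySpec, ...] = (
        RepeatFamilySpec("LTR/Gypsy", 45, LengthMixture(((0.6, 1500.0, 500.0), (0.4, 3000.0, 800.0)))),
        RepeatFamilySpec("LTR/Copia", 15, LengthMixture(((0.6, 1200.0, 400.0), (0.4, 2500.0, 700.0)))),
        RepeatFamilySpec("DNA/MULE-MuDR", 20, LengthMixture(((1.0, 800.0, 300.0),))),
        RepeatFamilySpec("LINE", 10, LengthMixture(((1.0, 1000.0, 400.0),))),
    )
    gene_count: int = 60
    gene_lengths: LengthMixture = LengthMixture(((1.0, 2400.0, 1200.0),))
    max_exons: int = 5
    max_isoforms: int = 2
    sample_count: int = 40
    sv_spec: SVSpec = SVSpec()
    orthogroup_spec: OrthogroupSpec = OrthogroupSpec()
    # factor by which repeat density inside gap flanks exceeds background
    gap_flank_repeat_boost: float = 1.0
    gap_flank_width: int = 1500
    # when False, repeats are placed independently of gap positions (a proper
    # null for the gap-flank permutation test); masked-fraction bookkeeping is
    # exact only when True, since gaps overwrite overlapping repeat bases
    repeats_avoid_gaps: bool = True


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    gaps: list[AssemblyGap]
    repeats: list[RepeatFeature]
    genes: list[GeneModel]
    repeat_bases: int  # exact planted repeat footprint

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{prefix}.genome.fa",
            "repeats": outdir / f"{prefix}.repeats.tsv",
            "genes": outdir / f"{prefix}.genes.gff3",
            "gaps": outdir / f"{prefix}.gaps.bed",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_repeat_table(self.repeats, paths["repeats"])
        write_gene_gff3(self.genes, paths["genes"])
        write_bed((g.interval for g in self.gaps), paths["gaps"])
        return paths


class PlacementError(RuntimeError):
    """Could not place all requested features without overlap."""


def _place_interval(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_lengths: Sequence[tuple[str, int]],
    length: int,
    max_tries: int = 200,
    within: GenomicInterval | None = None,
) -> GenomicInterval | None:
    """Place a non-overlapping interval, uniformly over eligible positions."""
    names = [n for n, _ in chrom_lengths]
    sizes = np.array([l for _, l in chrom_lengths], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(max_tries):
        if within is not None:
            chrom = within.chrom
            lo, hi = within.start, within.end - length
            if hi < lo:
                return None
            start = int(rng.integers(lo, hi + 1))
        else:
            idx = int(rng.choice(len(names), p=probs))
            chrom = names[idx]
            limit = int(sizes[idx]) - length
            if limit < 0:
                continue
            start = int(rng.integers(0, limit + 1))
        end = start + length
        clash = any(s < end and start < e for s, e in occupied.get(chrom, ()))
        if not clash:
            occupied.setdefault(chrom, []).append((start, end))
            return GenomicInterval(chrom, start, end)
    return None


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedGenome:
    """Generate a softmasked genome with planted gaps, repeats and genes.

    Gaps, genes and repeats are mutually non-overlapping except that repeats
    may fall inside genes (that overlap is the object of the genic-context
    analysis).  Repeat footprints never overlap each other or gaps, so the
    masked fraction of the emitted FASTA equals the planted repeat bases
    divided by the genome length exactly.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    chrom_lengths = list(config.chrom_lengths)
    lengths = {n: l for n, l in chrom_lengths}

    # 1. gaps
    hard: dict[str, list[tuple[int, int]]] = {}  # gaps (nothing may touch them)
    gaps: list[AssemblyGap] = []
    for _ in range(config.gap_count):
        iv = _place_interval(rng, hard, chrom_lengths, config.gap_length)
        if iv is None:
            raise PlacementError("could not place all gaps")
        gaps.append(AssemblyGap(iv))
    gaps.sort(key=lambda g: (g.interval.chrom, g.interval.start))

    # 2. genes: avoid gaps and each other
    gene_occ = {c: list(v) for c, v in hard.items()}
    genes: list[GeneModel] = []
    gene_sizes = config.gene_lengths.sample(rng, config.gene_count, min_len=150)
    for gi, size in enumerate(gene_sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        iv = _place_interval(rng, gene_occ, chrom_lengths, int(size))
        if iv is None:
            raise PlacementError("could not place all genes")
        span = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        genes.append(_make_gene(rng, f"gene{gi:05d}", span, config))
    genes.sort(key=lambda g: (g.span.chrom, g.span.start))

    # 3. repeats: avoid each other (and, by default, gaps); may overlap genes
    rep_occ = (
        {c: list(v) for c, v in hard.items()} if config.repeats_avoid_gaps else {}
    )
    flank_regions = _gap_flanks(gaps, lengths, config.gap_flank_width)
    flank_bases = sum(f.length for f in flank_regions)
    genome_bases = sum(lengths.values())
    boost = config.gap_flank_repeat_boost
    f = flank_bases / genome_bases if genome_bases else 0.0
    p_flank = boost * f / (1.0 + (boost - 1.0) * f) if boost > 1.0 and f > 0 else 0.0

    repeats: list[RepeatFeature] = []
    for fam in config.repeat_families:
        if "/" in fam.label:
            class_name, family_name = fam.label.split("/", 1)
        else:
            class_name, family_name = fam.label, ""
        rep_sizes = fam.lengths.sample(rng, fam.count)
        for size in rep_sizes:
            size = int(size)
            strand = "+" if rng.random() < 0.5 else "-"
            iv = None
            if fam.genic_bias > 0 and genes and rng.random() < fam.genic_bias:
                host = genes[int(rng.integers(len(genes)))]
                iv = _place_interval(
                    rng, rep_occ, chrom_lengths, size, within=host.span
                )
            elif p_flank > 0 and flank_regions and rng.random() < p_flank:
                order = rng.permutation(len(flank_regions))
                for j in order:
                    region = flank_regions[int(j)]
                    iv = _place_interval(
                        rng, rep_occ, chrom_lengths, size, max_tries=20, within=region
                    )
                    if iv is not None:
                        break
            if iv is None:
                iv = _place_interval(rng, rep_occ, chrom_lengths, size)
            if iv is None:
                raise PlacementError("could not place all repeats")
            repeats.append(
                RepeatFeature(
                    GenomicInterval(iv.chrom, iv.start, iv.end, strand),
                    class_name,
                    family_name,
                )
            )
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    # 4. materialize sequences
    sequences: dict[str, str] = {}
    arrays = {
        name: _random_sequence(rng, size, config.background_gc)
        for name, size in chrom_lengths
    }
    repeat_bases = 0
    for rep in repeats:
        iv = rep.interval
        seg = arrays[iv.chrom][iv.start : iv.end]
        arrays[iv.chrom][iv.start : iv.end] = np.char.lower(seg)
        repeat_bases += iv.length
    for gap in gaps:
        iv = gap.interval
        arrays[iv.chrom][iv.start : iv.end] = b"N"
    for name, _ in chrom_lengths:
        sequences[name] = arrays[name].tobytes().decode("ascii")

    return SimulatedGenome(sequences, gaps, repeats, genes, repeat_bases)


def _gap_flanks(
    gaps: Sequence[AssemblyGap], lengths: dict[str, int], width: int
) -> list[GenomicInterval]:
    regions = []
    for gap in gaps:
        iv = gap.interval
        if iv.start - width >= 0:
            regions.append(GenomicInterval(iv.chrom, iv.start - width, iv.start))
        if iv.end + width <= lengths[iv.chrom]:
            regions.append(GenomicInterval(iv.chrom, iv.end, iv.end + width))
    return regions


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    span: GenomicInterval,
    config: SimulationConfig,
) -> GeneModel:
    n_iso = int(rng.integers(1, config.max_isoforms + 1))
    transcripts = []
    for t in range(n_iso):
        n_exons = int(rng.integers(1, config.max_exons + 1))
        # 2n-1 alternating exon/intron chunks with random positive widths
        n_chunks = 2 * n_exons - 1
        w = rng.dirichlet(np.ones(n_chunks)) * span.length
        w = np.maximum(1, w.astype(int))
        # repair rounding so the chunks exactly tile the span
        w[-1] += span.length - int(w.sum())
        if w[-1] < 1:
            w = np.array([span.length], dtype=int)
            n_exons = 1
        bounds = np.concatenate([[0], np.cumsum(w)]) + span.start
        exons = tuple(
            GenomicInterval(span.chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]), span.strand)
            for i in range(n_exons)
        )
        aed = round(float(rng.beta(1.2, 4.0)), 3)
        transcripts.append(Transcript(f"{gene_id}.t{t + 1}", gene_id, exons, aed))
    return GeneModel(gene_id, span, tuple(transcripts))


# ---------------------------------------------------------------------------
# k-mer histogram


def simulate_kmer_histogram(
    genome_size: int,
    coverage: float,
    error_rate: float,
    seed: int | np.random.Generator = 0,
    k: int = 21,
):
    """Poisson coverage peak over ``genome_size`` distinct true k-mers plus a
    low-multiplicity error tail (one novel k-mer per erroneous base times k)."""
    from .io_formats import KmerHistogram

    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    rng = _as_rng(seed)
    true_mult = rng.poisson(coverage, size=genome_size)
    counts = np.bincount(true_mult)
    n_error = int(round(genome_size * coverage * error_rate * k / 2))
    if n_error > 0:
        err_mult = rng.geometric(0.85, size=n_error)
        err_counts = np.bincount(err_mult)
        size = max(len(counts), len(err_counts))
        counts = np.pad(counts, (0, size - len(counts)))
        counts += np.pad(err_counts, (0, size - len(err_counts)))
    bins = tuple(
        (int(m), int(c)) for m, c in enumerate(counts) if m >= 1 and c > 0
    )
    return KmerHistogram(k=k, bins=bins)


# ---------------------------------------------------------------------------
# SV population panel


@dataclass
class SimulatedSVPanel:
    records: list[SVRecord]
    samples: list[str]
    truth: list[dict]  # per record: id, sv_type, length, af, fate

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        import csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf = outdir / f"{prefix}.svs.vcf"
        truth = outdir / f"{prefix}.svs.truth.tsv"
        contigs: dict[str, int] = {}
        for rec in self.records:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end + 1)
        write_sv_vcf(self.records, self.samples, vcf, contigs=contigs)
        with open(truth, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["id", "sv_type", "length", "af", "fate"], delimiter="\t"
            )
            writer.writeheader()
            writer.writerows(self.truth)
        return {"vcf": vcf, "truth": truth}


def simulate_sv_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedSVPanel:
    """Delly-style SV panel: HWE genotypes at a per-variant allele frequency,
    plus designated records that each violate exactly one curation rule."""
    rng = _as_rng(config.seed if rng is None else rng)
    spec = config.sv_spec
    samples = [f"s{i:03d}" for i in range(config.sample_count)]
    chrom_names = [n for n, _ in config.chrom_lengths]

    records: list[SVRecord] = []
    truth: list[dict] = []
    counter = 0

    def emit(sv_type: str, fate: str) -> None:
        nonlocal counter
        counter += 1
        vid = f"SV{counter:05d}"
        mixture = spec.del_lengths if sv_type == "DEL" else spec.other_lengths
        length = int(mixture.sample(rng, 1)[0])
        precise, filt = True, "PASS"
        pe = int(5 + rng.poisson(8))
        sr = int(1 + rng.poisson(4))
        mapq = int(rng.integers(20, 61))
        if fate == "max_length":
            length = int(5_000_000 + rng.integers(0, 1_000_000))
        elif fate == "min_pe":
            pe = int(rng.integers(0, 5))
        elif fate == "imprecise":
            precise, sr = False, 0
        elif fate == "mapq":
            mapq = 0
        elif fate == "filter":
            filt = "LowQual"
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(1, 100_000))
        if spec.fixed_af is not None:
            af = spec.fixed_af
        else:
            af = float(rng.beta(spec.af_alpha, spec.af_beta)) / 2.0  # in [0, 0.5]
        alt_counts = rng.binomial(2, af, size=len(samples))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        genotypes = tuple(gt_map[int(a)] for a in alt_counts)
        records.append(
            SVRecord(
                id=vid,
                sv_type=sv_type,
                chrom=chrom,
                pos=pos,
                end=pos + length,
                precise=precise,
                pe=pe,
                sr=sr,
                mapq=mapq,
                filter_status=filt,
                genotypes=genotypes,
            )
        )
        truth.append(
            {"id": vid, "sv_type": sv_type, "length": length, "af": af, "fate": fate}
        )

    for sv_type, count in spec.counts.items():
        for _ in range(count):
            emit(sv_type, "pass")
    types = list(spec.counts)
    for rule in SV_FAIL_RULES:
        for _ in range(spec.fail_counts.get(rule, 0)):
            emit(types[int(rng.integers(len(types)))], rule)

    return SimulatedSVPanel(records, samples, truth)


# ---------------------------------------------------------------------------
# orthogroups / duplications / functional terms


@dataclass
class SimulatedOrthogroups:
    membership: list[tuple[str, str, str]]  # (orthogroup_id, species, gene_id)
    duplications: list[tuple[str, str, float, tuple[str, ...]]]
    annotations: dict[str, frozenset[str]]  # gene -> terms
    planted_node: str
    enriched_term: str
    focal_genes: list[str]

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "orthogroups": outdir / f"{prefix}.orthogroups.tsv",
            "duplications": outdir / f"{prefix}.duplications.tsv",
            "annotations": outdir / f"{prefix}.annotations.tsv",
        }
        with open(paths["orthogroups"], "w") as fh:
            fh.write("orthogroup\tspecies\tgene\n")
            for og, sp, gene in self.membership:
                fh.write(f"{og}\t{sp}\t{gene}\n")
        with open(paths["duplications"], "w") as fh:
            fh.write("node\torthogroup\tsupport\tgenes\n")
            for node, og, support, genes in self.duplications:
                fh.write(f"{node}\t{og}\t{support:g}\t{','.join(genes)}\n")
        with open(paths["annotations"], "w") as fh:
            fh.write("gene\tterm\n")
            for gene in sorted(self.annotations):
                for term in sorted(self.annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")
        return paths


def simulate_orthogroups(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedOrthogroups:
    """Orthogroup membership, node-assigned duplication events, and a term map
    with one term enriched among genes duplicated at the planted node."""
    rng = _as_rng(config.seed if rng is None else rng)
    spec = config.orthogroup_spec
    if len(spec.species) < 2:
        raise ValueError("need at least 2 species")

    membership: list[tuple[str, str, str]] = []
    og_focal_genes: dict[str, list[str]] = {}
    gene_counter = 0
    for i in range(spec.n_orthogroups):
        og = f"OG{i:05d}"
        og_focal_genes[og] = []
        for sp in spec.species:
            n = int(rng.integers(0, 4)) if sp != spec.focal_species else int(
                rng.integers(1, 4)
            )
            for _ in range(n):
                if sp == spec.focal_species:
                    gene = f"g{gene_counter:05d}"
                    gene_counter += 1
                    og_focal_genes[og].append(gene)
                else:
                    gene = f"{sp}_g{int(rng.integers(0, 10**6)):06d}"
                membership.append((og, sp, gene))

    og_ids = sorted(og_focal_genes)
    duplications: list[tuple[str, str, float, tuple[str, ...]]] = []
    planted_ogs: set[str] = set()

    def draw_support() -> float:
        if rng.random() < spec.low_support_fraction:
            return round(float(rng.uniform(0.3, 0.8999)), 4)
        return round(float(rng.uniform(0.90, 1.0)), 4)

    for node in spec.nodes:
        n_events = (
            spec.planted_events
            if node == spec.planted_node
            else spec.background_events_per_node
        )
        chosen = rng.choice(len(og_ids), size=min(n_events, len(og_ids)), replace=False)
        for j in chosen:
            og = og_ids[int(j)]
            genes = tuple(og_focal_genes[og][:2]) or (f"{spec.focal_species}_missing",)
            support = draw_support()
            duplications.append((node, og, support, genes))
            if node == spec.planted_node and support >= 0.90:
                planted_ogs.add(og)

    planted_genes = {
        g for og in planted_ogs for g in og_focal_genes[og][:2]
    }
    focal_genes = sorted(
        {g for _, sp, g in membership if sp == spec.focal_species}
    )
    terms = [f"T{i:03d}" for i in range(1, spec.n_terms + 1)]
    p_hit = min(1.0, spec.term_base_rate * spec.enrichment_effect)
    annotations: dict[str, frozenset[str]] = {}
    for gene in focal_genes:
        assigned = set()
        for term in terms:
            rate = spec.term_base_rate
            if term == spec.enriched_term and gene in planted_genes:
                rate = p_hit
            if rng.random() < rate:
                assigned.add(term)
        annotations[gene] = frozenset(assigned)

    return SimulatedOrthogroups(
        membership=membership,
        duplications=duplications,
        annotations=annotations,
        planted_node=spec.planted_node,
        enriched_term=spec.enriched_term,
        focal_genes=focal_genes,
    )
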