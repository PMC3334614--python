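"""Synthetic allohexaploid grain transcriptome generator.

Emulates the data structure an allopolyploid duplicate-fate analysis
assumes: a diploid reference genome (the stand-in for a sequenced relative
such as *Brachypodium*), three homoeologous subgenomes (A/B/D) derived from
it with a configurable homoeoSNP density (default 1 per 500 bp), ancestral
whole-genome-duplication (WGD) paralog blocks, tandem copy-number variants,
per-copy stage-presence expression profiles over a grain developmental
kinetic (default five stages), and shotgun cDNA-style reads at a target
depth (default 25x per transcript copy, read lengths 400-900 b).

Every planted relationship (paralog partnerships, tandem parents, deleted
homoeologs, expression divergence, read provenance) is recorded in truth
tables so each downstream analysis stage can be scored without external
data.  Identical config + seed produces bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SUBGENOMES = ("A", "B", "D")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic allohexaploid transcriptome.

    ``homoeolog_snp_rate`` is the *pairwise* homoeoSNP density between
    sibling subgenome copies (substitutions per base); each copy is mutated
    away from the reference at half that rate so that any two siblings
    differ at approximately ``rate * length`` positions.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 50
    gene_length_mean: int = 1000
    paralog_block_fraction: float = 0.0
    paralog_block_pairs: int = 5
    paralog_divergence: float = 0.12
    paralog_loss_prob: float = 0.0
    homoeolog_snp_rate: float = 1.0 / 500.0
    homoeolog_loss_prob: float = 0.0
    homoeolog_identical_fraction: float = 0.0
    snp_placement: str = "random"  # "random" | "even"
    expr_divergence_prob: float = 0.0
    cnv_prob: float = 0.0
    mean_coverage: float = 25.0
    read_length_range: tuple[int, int] = (400, 900)
    n_stages: int = 5
    stage_presence_prob: float = 0.7
    intergenic_length: int = 200
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
            "gene_length_mean": self.gene_length_mean,
            "n_stages": self.n_stages,
            "paralog_block_pairs": self.paralog_block_pairs,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        probs = {
            "paralog_block_fraction": self.paralog_block_fraction,
            "paralog_loss_prob": self.paralog_loss_prob,
            "homoeolog_loss_prob": self.homoeolog_loss_prob,
            "homoeolog_identical_fraction": self.homoeolog_identical_fraction,
            "expr_divergence_prob": self.expr_divergence_prob,
            "cnv_prob": self.cnv_prob,
            "stage_presence_prob": self.stage_presence_prob,
            "paralog_divergence": self.paralog_divergence,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.homoeolog_snp_rate <= 0.05:
            raise ConfigurationError(
                f"homoeolog_snp_rate must lie in (0, 0.05], got {self.homoeolog_snp_rate!r}"
            )
        lo, hi = self.read_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"read_length_range must be 0 < min <= max, got {(lo, hi)!r}")
        if self.mean_coverage < 0:
            raise ConfigurationError("mean_coverage must be non-negative")
        if self.snp_placement not in ("random", "even"):
            raise ConfigurationError(f"snp_placement must be 'random' or 'even', got {self.snp_placement!r}")
        if self.paralog_block_fraction > 0 and self.n_chromosomes < 2:
            raise ConfigurationError("paralog blocks require at least two chromosomes")


@dataclass
class GeneModel:
    """One annotated reference gene (0-based, half-open coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    paralog_partner: Optional[str] = None
    tandem_parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.paralog_partner == self.gene_id:
            raise ValueError(f"{self.gene_id}: a gene cannot be its own paralog partner")


@dataclass
class Genome:
    genes: list[GeneModel]
    gene_sequences: dict[str, str]
    chromosome_sequences: dict[str, str]
    truth: pd.DataFrame

    def gene(self, gene_id: str) -> GeneModel:
        return self._index[gene_id]

    def __post_init__(self) -> None:
        self._index = {g.gene_id: g for g in self.genes}


@dataclass
class TranscriptCopy:
    """One homoeologous copy of a reference gene in the hexaploid.

    ``presence`` / ``levels`` are the per-stage expression truth; a deleted
    copy never yields reads.
    """

    gene_id: str
    subgenome: str
    sequence: str
    deleted: bool
    presence: tuple[bool, ...]
    levels: tuple[float, ...]
    diverged: bool = False
    n_snps_from_ref: int = 0

    @property
    def copy_id(self) -> str:
        return f"{self.gene_id}_{self.subgenome}"

    @property
    def expressed(self) -> bool:
        return not self.deleted and any(self.presence)


@dataclass
class Read:
    read_id: str
    sequence: str


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitution-only mutation: each base replaced, with probability
    ``rate``, by a uniformly chosen different base.  No indels."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), int(hits.size)


def generate_genome(config: SimulationConfig) -> Genome:
    """Generate the reference genome with planted paralog blocks and tandem
    CNV copies.

    Paralog blocks are collinear runs of ``paralog_block_pairs`` genes whose
    partners sit, in the same order, on a different chromosome; exactly
    ``round(paralog_block_fraction * n_genes)`` genes (rounded down to an
    even count) are partnered.  A fraction ``cnv_prob`` of genes receive a
    tandem copy inserted immediately downstream on the same chromosome,
    whose sequence inherits the parent's with fresh substitutions at the
    homoeoSNP rate, so tandem copies are distinguishable from homoeologs
    only by genomic position.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    n_chrom = config.n_chromosomes
    n_per = config.genes_per_chromosome
    chrom_names = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    gene_ids = [[f"{chrom_names[c]}g{i + 1:04d}" for i in range(n_per)] for c in range(n_chrom)]

    # Lengths and base sequences.
    sd = max(1.0, config.gene_length_mean / 5.0)
    min_len = max(60, config.gene_length_mean // 3)
    sequences: dict[str, str] = {}
    for c in range(n_chrom):
        for gid in gene_ids[c]:
            length = max(min_len, int(round(rng.normal(config.gene_length_mean, sd))))
            sequences[gid] = _random_sequence(rng, length)

    # Paralog blocks: pair collinear runs on different chromosomes.
    n_total = n_chrom * n_per
    n_partnered = 2 * (int(round(config.paralog_block_fraction * n_total)) // 2)
    partner: dict[str, str] = {}
    block_of: dict[str, int] = {}
    cursors = [0] * n_chrom
    block_id = 0
    pairs_left = n_partnered // 2
    while pairs_left > 0:
        src_chrom = block_id % n_chrom
        dst_chrom = (src_chrom + 1) % n_chrom
        size = min(config.paralog_block_pairs, pairs_left)
        if cursors[src_chrom] + size > n_per or cursors[dst_chrom] + size > n_per:
            raise ConfigurationError("paralog_block_fraction too high for genome size")
        for k in range(size):
            a = gene_ids[src_chrom][cursors[src_chrom] + k]
            b = gene_ids[dst_chrom][cursors[dst_chrom] + k]
            partner[a] = b
            partner[b] = a
            block_of[a] = block_id
            block_of[b] = block_id
            # Partner derives from the source gene at paleoduplicate divergence.
            sequences[b], _ = _mutate(rng, sequences[a], config.paralog_divergence)
        cursors[src_chrom] += size
        cursors[dst_chrom] += size
        pairs_left -= size
        block_id += 1

    # Tandem CNV copies, inserted immediately after their parents.
    tandem_parent: dict[str, str] = {}
    ordered_ids: list[list[str]] = []
    for c in range(n_chrom):
        ordered = []
        for gid in gene_ids[c]:
            ordered.append(gid)
            if rng.random() < config.cnv_prob:
                tid = f"{gid}t"
                sequences[tid], _ = _mutate(rng, sequences[gid], config.homoeolog_snp_rate)
                tandem_parent[tid] = gid
                ordered.append(tid)
        ordered_ids.append(ordered)

    # Chromosome layout: spacer + gene, strands random.
    genes: list[GeneModel] = []
    chrom_seqs: dict[str, str] = {}
    for c in range(n_chrom):
        parts: list[str] = []
        pos = 0
        for gid in ordered_ids[c]:
            spacer = _random_sequence(rng, config.intergenic_length)
            parts.append(spacer)
            pos += len(spacer)
            seq = sequences[gid]
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(seq if strand == "+" else reverse_complement(seq))
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom_names[c],
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                    paralog_partner=partner.get(gid),
                    tandem_parent=tandem_parent.get(gid),
                )
            )
            pos += len(seq)
        parts.append(_random_sequence(rng, config.intergenic_length))
        chrom_seqs[chrom_names[c]] = "".join(parts)

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chromosome": [g.chromosome for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.end - g.start for g in genes],
            "paralog_partner": [g.paralog_partner or "" for g in genes],
            "paralog_block": [block_of.get(g.gene_id, -1) for g in genes],
            "tandem_parent": [g.tandem_parent or "" for g in genes],
        }
    )
    return Genome(genes=genes, gene_sequences=sequences, chromosome_sequences=chrom_seqs, truth=truth)


def _homoeosnp_sequences(
    rng: np.random.Generator, ref: str, rate: float, placement: str
) -> tuple[list[str], list[int]]:
    """Three subgenome sequences whose pairwise homoeoSNP density is ``rate``.

    ``random`` placement mutates each copy independently at rate/2.
    ``even`` placement plants SNP columns every round(1/rate) bases and gives
    the three copies three distinct bases there, so every window of
    ``round(1/rate)`` or more bases carries at least one pairwise difference
    between any two siblings (used to make read clustering separate
    homoeologs deterministically).
    """
    if placement == "random":
        out, ns = [], []
        for _ in SUBGENOMES:
            seq, n = _mutate(rng, ref, rate / 2.0)
            out.append(seq)
            ns.append(n)
        return out, ns
    spacing = max(2, int(round(1.0 / rate)))
    arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    positions = np.arange(spacing // 2, arr.size, spacing)
    copies = [arr.copy() for _ in SUBGENOMES]
    for p in positions:
        alts = rng.permutation(_BASES)[:3]
        for copy, base in zip(copies, alts):
            copy[p] = base
    ns = [int(np.sum(c != arr)) for c in copies]
    return [c.tobytes().decode() for c in copies], ns


def generate_hexaploid(genome: Genome, config: SimulationConfig) -> list[TranscriptCopy]:
    """Derive A/B/D transcript copies for every reference gene.

    Each gene yields three copies; paleoparalog members may be lost wholesale
    (``paralog_loss_prob``, modelling pre-polyploidy pseudogenization) and
    each copy is further deleted independently with ``homoeolog_loss_prob``.
    Retained copies carry homoeoSNPs and a stage-presence profile diverged
    from the gene's ancestral profile with ``expr_divergence_prob``; a drawn
    divergence always flips at least one stage flag.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    copies: list[TranscriptCopy] = []
    for gene in genome.genes:
        ref = genome.gene_sequences[gene.gene_id]
        identical = rng.random() < config.homoeolog_identical_fraction
        gene_lost = bool(gene.paralog_partner) and rng.random() < config.paralog_loss_prob

        # Ancestral stage-presence profile (shared by the three copies).
        while True:
            ancestral = rng.random(config.n_stages) < config.stage_presence_prob
            if ancestral.any():
                break
        ancestral_levels = np.where(ancestral, np.exp(rng.normal(2.0, 0.6, config.n_stages)), 0.0)

        if identical:
            seqs, n_snps = [ref] * 3, [0] * 3
        else:
            seqs, n_snps = _homoeosnp_sequences(
                rng, ref, config.homoeolog_snp_rate, config.snp_placement
            )

        for sub, seq, nsnp in zip(SUBGENOMES, seqs, n_snps):
            deleted = gene_lost or (rng.random() < config.homoeolog_loss_prob)
            presence = ancestral.copy()
            levels = ancestral_levels.copy()
            diverged = False
            if not deleted and rng.random() < config.expr_divergence_prob:
                diverged = True
                flips = rng.random(config.n_stages) < 1.0 / config.n_stages
                if not flips.any():
                    flips[rng.integers(config.n_stages)] = True
                presence = presence ^ flips
                levels = np.where(
                    presence & ~ancestral, np.exp(rng.normal(2.0, 0.6, config.n_stages)), levels
                )
                levels = np.where(presence, levels, 0.0)
            copies.append(
                TranscriptCopy(
                    gene_id=gene.gene_id,
                    subgenome=sub,
                    sequence=seq,
                    deleted=deleted,
                    presence=tuple(bool(x) for x in presence),
                    levels=tuple(float(x) for x in levels),
                    diverged=diverged,
                    n_snps_from_ref=nsnp,
                )
            )
    return copies


def copies_truth_table(copies: Sequence[TranscriptCopy]) -> pd.DataFrame:
    """Tabulate the planted per-copy truth (deletion, divergence, SNPs)."""
    return pd.DataFrame(
        {
            "copy_id": [c.copy_id for c in copies],
            "gene_id": [c.gene_id for c in copies],
            "subgenome": [c.subgenome for c in copies],
            "deleted": [c.deleted for c in copies],
            "diverged": [c.diverged for c in copies],
            "expressed": [c.expressed for c in copies],
            "n_snps_from_ref": [c.n_snps_from_ref for c in copies],
            "presence": ["".join("1" if p else "0" for p in c.presence) for c in copies],
        }
    )


def sample_reads(
    copies: Sequence[TranscriptCopy], config: SimulationConfig
) -> tuple[list[Read], pd.DataFrame]:
    """Sample unstranded shotgun reads from expressed copies.

    Per-copy read counts are Poisson with mean ``mean_coverage * L / E[read
    length]`` so the expected depth per copy equals ``mean_coverage``; read
    lengths are uniform in ``read_length_range`` (clipped to the copy
    length).  Read ids are opaque and the emitted order is shuffled; the
    returned truth table maps each read to its source copy.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 37])
    lo, hi = config.read_length_range
    mean_rl = (lo + hi) / 2.0
    drawn: list[tuple[str, str, str, int, str, str]] = []
    for copy in copies:
        if not copy.expressed:
            continue
        length = len(copy.sequence)
        lam = config.mean_coverage * length / mean_rl
        n_reads = rng.poisson(lam) if lam > 0 else 0
        for _ in range(n_reads):
            rl = min(int(rng.integers(lo, hi + 1)), length)
            start = int(rng.integers(0, length - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = copy.sequence[start : start + rl]
            if strand == "-":
                seq = reverse_complement(seq)
            drawn.append((copy.copy_id, copy.gene_id, copy.subgenome, start, strand, seq))
    order = rng.permutation(len(drawn))
    reads: list[Read] = []
    rows = []
    for i, j in enumerate(order):
        copy_id, gene_id, sub, start, strand, seq = drawn[j]
        rid = f"read{i + 1:07d}"
        reads.append(Read(read_id=rid, sequence=seq))
        rows.append((rid, copy_id, gene_id, sub, start, strand, len(seq)))
    truth = pd.DataFrame(
        rows, columns=["read_id", "copy_id", "gene_id", "subgenome", "start", "strand", "length"]
    )
    return reads, truth


# ---------------------------------------------------------------------------
# On-disk outputs


def write_fasta(path: Path, records: Sequence[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path: Path, genome: Genome) -> None:
    """Emit gene models as GFF3 (1-based, closed intervals on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.chromosome_sequences.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.paralog_partner:
                attrs.append(f"paralog_partner={g.paralog_partner}")
            if g.tandem_parent:
                attrs.append(f"tandem_parent={g.tandem_parent}")
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "polyfate",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def expression_truth_table(copies: Sequence[TranscriptCopy], n_stages: int) -> pd.DataFrame:
    cols = {f"stage_{s + 1}": [c.levels[s] for c in copies] for s in range(n_stages)}
    return pd.DataFrame({"copy_id": [c.copy_id for c in copies], **cols})


def simulate_to_dir(config: SimulationConfig, outdir: Path) -> dict[str, Path]:
    """Run the full generator and write all artefacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    copies = generate_hexaploid(genome, config)
    reads, read_truth = sample_reads(copies, config)

    paths = {
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.gff3",
        "reads": outdir / "reads.fasta",
        "truth_copies": outdir / "truth_copies.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "expression_truth": outdir / "expression_truth.tsv",
    }
    write_fasta(paths["genome"], sorted(genome.chromosome_sequences.items()))
    write_gff3(paths["genes"], genome)
    write_fasta(paths["reads"], [(r.read_id, r.sequence) for r in reads])
    copies_truth_table(copies).to_csv(paths["truth_copies"], sep="\t", index=False)
    read_truth.to_csv(paths["truth_reads"], sep="\t", index=False)
    expression_truth_table(copies, config.n_stages).to_csv(
        paths["expression_truth"], sep="\t", index=False
    )
    return paths


def config_from_yaml(path: Path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "read_length_range" in raw:
        raw["read_length_range"] = tuple(raw["read_length_range"])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
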