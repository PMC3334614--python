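"""CIP/CALP homology scoring and duplicate-relationship classification.

The ortholog filter rebuilds, for each query-subject pair, all BLAST-style
high-scoring pairs (HSPs) into three summary statistics:

* AL    - aligned length: the total merged query span of the HSPs;
* CIP   - cumulative identity percentage: 100 * (sum of identities) / AL;
* CALP  - cumulative alignment length percentage: AL / query length.

A pair passing CIP >= 60 and CALP >= 0.70 (boundaries inclusive) is a
candidate one-to-one ortholog (COS); the best subject per query wins.
Overlapping HSPs are merged on the query before AL is computed, keeping the
higher-bitscore HSP in the contested region with identities prorated, so
CALP can never exceed 1.

On top of the ortholog pairs the module classifies reference genes into
COS / CNV (tandem duplicates) / PAV (no conserved match), counts homoeolog
copies per reference gene (1/2/3), flags putatively merged homoeologous
clusters from read-coverage excess, and summarizes the retention of
ancestral WGD paralog pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import GeneModel


@dataclass(frozen=True)
class HSP:
    """One local alignment segment (0-based half-open coordinates)."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    length: int
    n_identities: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise ValueError("q_start must be < q_end")
        if not 0 <= self.n_identities <= self.length:
            raise ValueError("n_identities must lie in [0, length]")


@dataclass(frozen=True)
class AlignmentScore:
    query_id: str
    subject_id: str
    AL: int
    CIP: float
    CALP: float
    n_hsps: int


@dataclass
class HomologyCall:
    reference_gene_id: str
    relation: str  # COS | CNV | PAV
    homoeolog_copy_count: int
    matched_cluster_ids: list[str]
    supernumerary: int = 0


@dataclass(frozen=True)
class ParalogPair:
    gene_a_id: str
    gene_b_id: str
    duplication_id: int = -1

    def __post_init__(self) -> None:
        if self.gene_a_id == self.gene_b_id:
            raise ValueError("a paralog pair must join two distinct genes")


def _hsp_priority(h: HSP) -> tuple:
    # Higher bitscore wins contested query columns; remaining keys only
    # break exact ties deterministically.
    return (-h.bitscore, h.q_start, h.q_end, h.s_start, h.subject_id)


def score_alignment(hsps: Sequence[HSP], query_length: int) -> AlignmentScore:
    """Merge the HSPs of one query-subject pair into an AL/CIP/CALP summary.

    Identities of a partially masked HSP are prorated by the retained
    fraction of its query span.
    """
    if not hsps:
        raise ValueError("score_alignment requires at least one HSP")
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    qid = hsps[0].query_id
    sid = hsps[0].subject_id
    for h in hsps:
        if h.query_id != qid or h.subject_id != sid:
            raise ValueError("all HSPs must share one query and one subject")

    covered: list[tuple[int, int]] = []  # disjoint, sorted
    al = 0
    identities = 0.0
    for h in sorted(hsps, key=_hsp_priority):
        span = h.q_end - h.q_start
        retained = 0
        # Subtract already-covered intervals from this HSP's query span.
        cursor = h.q_start
        for cs, ce in covered:
            if ce <= h.q_start or cs >= h.q_end:
                continue
            if cs > cursor:
                retained += min(cs, h.q_end) - cursor
            cursor = max(cursor, ce)
            if cursor >= h.q_end:
                break
        if cursor < h.q_end:
            retained += h.q_end - cursor
        if retained > 0:
            al += retained
            identities += h.n_identities * (retained / span)
        covered.append((h.q_start, h.q_end))
        covered = _merge_intervals(covered)

    cip = 100.0 * identities / al if al else 0.0
    calp = al / query_length
    return AlignmentScore(query_id=qid, subject_id=sid, AL=al, CIP=cip, CALP=calp, n_hsps=len(hsps))


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def score_all(hsps: Iterable[HSP], query_lengths: Mapping[str, int]) -> list[AlignmentScore]:
    """Group HSPs by (query, subject) and score every pair."""
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.query_id, h.subject_id), []).append(h)
    return [
        score_alignment(group, query_lengths[qid]) for (qid, _sid), group in sorted(groups.items())
    ]


def call_orthologs(
    scores: Sequence[AlignmentScore], cip_min: float = 60.0, calp_min: float = 0.70
) -> list[tuple[str, str]]:
    """Retain pairs passing the CIP/CALP thresholds (inclusive) and keep,
    per query, the best subject (highest CIP, ties by CALP, then subject id).
    """
    best: dict[str, AlignmentScore] = {}
    for s in scores:
        if s.CIP < cip_min or s.CALP < calp_min:
            continue
        cur = best.get(s.query_id)
        if cur is None or (-s.CIP, -s.CALP, s.subject_id) < (-cur.CIP, -cur.CALP, cur.subject_id):
            best[s.query_id] = s
    return sorted((s.query_id, s.subject_id) for s in best.values())


def call_domain_homologs(
    protein_scores: pd.DataFrame, identity_min: float = 0.50
) -> tuple[dict[str, set[str]], list[str]]:
    """Protein-level homolog sets per reference proteome.

    ``protein_scores`` has columns cluster_id, proteome, identity (proportion
    in [0, 1]); a cluster is a homolog of a proteome if any subject reaches
    ``identity_min``.  Returns (cluster -> proteome set, species-specific
    cluster ids).
    """
    hits = protein_scores[protein_scores["identity"] >= identity_min]
    homologs = {
        cid: set(group["proteome"]) for cid, group in hits.groupby("cluster_id", sort=True)
    }
    all_clusters = sorted(set(protein_scores["cluster_id"]))
    specific = [c for c in all_clusters if c not in homologs]
    return homologs, specific


def shared_proteome_counts(homologs: Mapping[str, set[str]]) -> dict[int, int]:
    """Venn-style tally: how many clusters hit exactly k proteomes."""
    counts: dict[int, int] = {}
    for proteomes in homologs.values():
        k = len(proteomes)
        counts[k] = counts.get(k, 0) + 1
    return counts


def classify_cnv_pav(
    cos_pairs: Sequence[tuple[str, str]],
    reference_gene_models: Sequence[GeneModel],
    tandem_window: int = 1,
) -> list[HomologyCall]:
    """Classify every reference gene as COS, CNV, or PAV.

    PAV: no passing match.  CNV: the gene is matched and belongs to a tandem
    duplication whose partner (annotated via ``tandem_parent`` and lying
    within ``tandem_window`` gene positions on the same chromosome) is also
    matched.  Otherwise COS.  Copy counts are capped at 3; matches beyond
    three are reported as ``supernumerary``, never silently merged.
    """
    by_id = {g.gene_id: g for g in reference_gene_models}
    matched: dict[str, list[str]] = {}
    for cluster, gene in cos_pairs:
        if gene not in by_id:
            raise ValueError(f"unknown reference gene id in cos_pairs: {gene!r}")
        matched.setdefault(gene, []).append(cluster)

    # Gene rank along each chromosome (by start) for the tandem window test.
    rank: dict[str, int] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in reference_gene_models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        for r, g in enumerate(sorted(chrom_genes, key=lambda x: x.start)):
            rank[g.gene_id] = r

    def tandem_partners(g: GeneModel) -> list[GeneModel]:
        out = []
        if g.tandem_parent and g.tandem_parent in by_id:
            out.append(by_id[g.tandem_parent])
        for other in reference_gene_models:
            if other.tandem_parent == g.gene_id:
                out.append(other)
        return [
            p
            for p in out
            if p.chromosome == g.chromosome and abs(rank[p.gene_id] - rank[g.gene_id]) <= tandem_window
        ]

    calls: list[HomologyCall] = []
    for g in sorted(reference_gene_models, key=lambda x: x.gene_id):
        clusters = sorted(matched.get(g.gene_id, []))
        if not clusters:
            calls.append(HomologyCall(g.gene_id, "PAV", 0, []))
            continue
        relation = "COS"
        if any(p.gene_id in matched for p in tandem_partners(g)):
            relation = "CNV"
        copy_count = min(len(clusters), 3)
        calls.append(
            HomologyCall(
                g.gene_id,
                relation,
                copy_count,
                clusters,
                supernumerary=max(0, len(clusters) - 3),
            )
        )
    return calls


def count_homoeolog_copies(
    cos_pairs: Sequence[tuple[str, str]],
) -> tuple[dict[int, int], float]:
    """Histogram of distinct matched clusters per reference gene (capped at
    3) and the triplet fraction 100 * n3 / (n1 + n2 + n3), one decimal."""
    per_gene: dict[str, set[str]] = {}
    for cluster, gene in cos_pairs:
        per_gene.setdefault(gene, set()).add(cluster)
    hist = {1: 0, 2: 0, 3: 0}
    for clusters in per_gene.values():
        hist[min(len(clusters), 3)] += 1
    total = sum(hist.values())
    triplet_fraction = round_half_up(100.0 * hist[3] / total, 1) if total else 0.0
    return hist, triplet_fraction


def triplet_fraction_from_histogram(hist: Mapping[int, int]) -> float:
    total = hist.get(1, 0) + hist.get(2, 0) + hist.get(3, 0)
    if total == 0:
        return 0.0
    return round_half_up(100.0 * hist.get(3, 0) / total, 1)


def flag_merged_homoeologs(
    coverage_table: pd.DataFrame, k: float = 3.5
) -> tuple[list[str], float]:
    """Flag clusters whose read count exceeds ``k`` times the global mean.

    The default multiplier reproduces the published operating point where a
    >140-read threshold sits against a ~38-42 read single-copy mean.
    Returns (flagged cluster ids, flagged fraction of all clusters).
    """
    if len(coverage_table) == 0:
        raise ValueError("coverage table must contain at least one cluster")
    mean_reads = float(coverage_table["n_reads"].mean())
    mask = coverage_table["n_reads"] > k * mean_reads
    flagged = sorted(coverage_table.loc[mask, "cluster_id"])
    return flagged, len(flagged) / len(coverage_table)


def paralog_pair_status(
    paralog_pairs: Sequence[ParalogPair | tuple[str, str]],
    matched_reference_genes: set[str],
) -> dict[str, float | int]:
    """Per-pair retention status against the set of reference genes with at
    least one expressed match; percentages to one decimal (half-up)."""
    both = one = none = 0
    for pair in paralog_pairs:
        a, b = (pair.gene_a_id, pair.gene_b_id) if isinstance(pair, ParalogPair) else pair
        n = (a in matched_reference_genes) + (b in matched_reference_genes)
        if n == 2:
            both += 1
        elif n == 1:
            one += 1
        else:
            none += 1
    total = both + one + none
    both_pct = round_half_up(100.0 * both / total, 1) if total else 0.0
    not_both_pct = round_half_up(100.0 * (one + none) / total, 1) if total else 0.0
    return {
        "both": both,
        "one": one,
        "none": none,
        "total": total,
        "both_matched_pct": both_pct,
        "not_both_matched_pct": not_both_pct,
    }


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always up), matching printed tables."""
    factor = 10.0 ** ndigits
    return np.floor(x * factor + 0.5) / factor


# ---------------------------------------------------------------------------
# Tabular alignment I/O (12-column BLAST-style format)

M8_COLUMNS = [
    "qid",
    "sid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_m8(path) -> list[HSP]:
    """Parse 12-column tabular alignments (1-based inclusive coordinates on
    disk, converted to 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", names=M8_COLUMNS, comment="#")
    hsps = []
    for row in df.itertuples(index=False):
        qs, qe = sorted((int(row.qstart), int(row.qend)))
        ss, se = sorted((int(row.sstart), int(row.send)))
        length = int(row.length)
        hsps.append(
            HSP(
                query_id=str(row.qid),
                subject_id=str(row.sid),
                q_start=qs - 1,
                q_end=qe,
                s_start=ss - 1,
                s_end=se,
                length=length,
                n_identities=int(round(row.pident * length / 100.0)),
                bitscore=float(row.bitscore),
            )
        )
    return hsps


def write_m8(path, hsps: Sequence[HSP]) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            pident = 100.0 * h.n_identities / h.length
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id,
                        h.subject_id,
                        f"{pident:.2f}",
                        h.length,
                        h.length - h.n_identities,
                        0,
                        h.q_start + 1,
                        h.q_end,
                        h.s_start + 1,
                        h.s_end,
                        "0.0",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Exact toy aligner (test/demo substitute for an external aligner)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmers(codes: np.ndarray, k: int) -> np.ndarray:
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    vals = win @ (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    vals[(win >= 4).any(axis=1)] = -1
    return vals


def diagonal_align(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    k: int = 16,
    min_hsp_len: int = 30,
    min_hsp_identity: float = 0.50,
    max_diagonals: int = 5,
) -> list[HSP]:
    """Ungapped seed-and-extend aligner for substitution-only sequences.

    For each query-subject pair sharing a k-mer, the full overlap along each
    seeded diagonal becomes one candidate HSP (both query strands are tried;
    the better strand's HSPs are emitted with coordinates on that strand).
    Suitable as the exact oracle aligner for simulated data; not a general
    gapped aligner.
    """
    from .simulate import reverse_complement

    subj_codes = {sid: _encode(s) for sid, s in subjects.items()}
    index: dict[int, list[tuple[str, int]]] = {}
    step = 4
    for sid, sc in subj_codes.items():
        kv = _kmers(sc, k)
        for p in range(0, kv.size, step):
            v = int(kv[p])
            if v >= 0:
                index.setdefault(v, []).append((sid, p))

    out: list[HSP] = []
    for qid, qseq in sorted(queries.items()):
        per_strand: dict[int, list[HSP]] = {0: [], 1: []}
        totals = {0: 0, 1: 0}
        for strand, seq in enumerate((qseq, reverse_complement(qseq))):
            qc = _encode(seq)
            kv = _kmers(qc, k)
            diags: dict[tuple[str, int], int] = {}
            for p in range(kv.size):
                v = int(kv[p])
                if v < 0:
                    continue
                for sid, sp in index.get(v, ()):
                    key = (sid, p - sp)
                    diags[key] = diags.get(key, 0) + 1
            per_subject: dict[str, list[tuple[int, int]]] = {}
            for (sid, d), cnt in diags.items():
                per_subject.setdefault(sid, []).append((cnt, d))
            for sid, dlist in per_subject.items():
                sc = subj_codes[sid]
                for _cnt, d in sorted(dlist, key=lambda x: (-x[0], x[1]))[:max_diagonals]:
                    q0 = max(0, d)
                    q1 = min(qc.size, d + sc.size)
                    if q1 - q0 < min_hsp_len:
                        continue
                    a = qc[q0:q1]
                    b = sc[q0 - d : q1 - d]
                    nid = int(np.sum((a == b) & (a < 4)))
                    length = q1 - q0
                    if nid / length < min_hsp_identity:
                        continue
                    hsp = HSP(
                        query_id=qid,
                        subject_id=sid,
                        q_start=q0,
                        q_end=q1,
                        s_start=q0 - d,
                        s_end=q1 - d,
                        length=length,
                        n_identities=nid,
                        bitscore=2.0 * nid - 3.0 * (length - nid),
                    )
                    per_strand[strand].append(hsp)
                    totals[strand] += nid
        out.extend(per_strand[0] if totals[0] >= totals[1] else per_strand[1])
    return out
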