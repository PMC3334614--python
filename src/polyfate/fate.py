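"""Duplicate-fate statistics: structural loss and expression divergence.

Quantifies what happened to duplicated gene copies after polyploidization:

* per-gene homoeolog triplet fates (structural loss, expression divergence
  within the grain developmental kinetic, divergence between tissues, full
  conservation) and their summary percentages;
* concerted presence/absence (PAV) expression across two species' ortholog
  pairs, optionally crediting paralogs that kept the ancestral profile;
* chi-square bias of Gene Ontology categories between an expressed gene set
  and the genome-wide background;
* whole-genome-duplication enrichment of a metabolic gene network and the
  reconstructed pre-WGD network size;
* a plain equal-variance two-group t-test per gene with variance-extreme
  exclusion and Bonferroni control.

Two deliberately different rounding rules reproduce the source tables these
statistics are usually reported in: assay-level percentages are rounded
half-up to integers, PAV concertation percentages are *truncated* to one
decimal (38.46% prints as 38.4%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import round_half_up


@dataclass(frozen=True)
class PresenceProfile:
    """Binary per-stage expression profile (optionally with abundances)."""

    entity_id: str
    presence: tuple[bool, ...]
    levels: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if len(self.presence) < 1:
            raise ValueError("a presence profile needs at least one stage")


@dataclass
class FateSummary:
    n_assigned: int  # genes with successful structural (copy) assignment
    n_expression_assayed: int  # genes with scored expression profiles
    n_structural_loss: int
    n_expr_loss_within: int
    n_expr_loss_between: int
    n_fully_conserved: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_structural_loss > self.n_assigned or self.n_fully_conserved > self.n_assigned:
            raise ValueError("structural counts exceed their denominator")
        if (
            self.n_expr_loss_within > self.n_expression_assayed
            or self.n_expr_loss_between > self.n_expression_assayed
        ):
            raise ValueError("expression counts exceed their denominator")
        self.percentages = {
            "structural_loss": round_half_up(100.0 * self.n_structural_loss / self.n_assigned),
            "expr_loss_within": round_half_up(
                100.0 * self.n_expr_loss_within / self.n_expression_assayed
            ),
            "expr_loss_between": round_half_up(
                100.0 * self.n_expr_loss_between / self.n_expression_assayed
            ),
            "fully_conserved": round_half_up(100.0 * self.n_fully_conserved / self.n_assigned),
        }


@dataclass(frozen=True)
class GOCategoryCount:
    category: str
    observed: int  # count in the expressed (grain) set
    background: int  # count genome-wide

    def __post_init__(self) -> None:
        if self.observed < 0 or self.background < 0:
            raise ValueError("GO counts must be non-negative")


def call_presence(levels: Sequence[float], threshold: float) -> tuple[bool, ...]:
    """Binarize abundance levels: present iff level > threshold."""
    if any(v < 0 for v in levels):
        raise ValueError("abundance levels must be non-negative")
    return tuple(v > threshold for v in levels)


STRUCTURAL_LOSS = "structural_loss"
DIVERGED_WITHIN = "diverged_within_kinetic"
DIVERGED_BETWEEN = "diverged_between_tissues"
CONSERVED = "conserved"


def classify_triplet_fate(
    grain_profiles: Mapping[str, Sequence[bool]],
    copies_detected: set[str],
    tissue_profiles: Optional[Mapping[str, Sequence[bool]]] = None,
) -> set[str]:
    """Fate labels for one gene's homoeolog triplet.

    ``grain_profiles`` maps detected copy ids to their stage-presence flags
    over the grain kinetic; ``tissue_profiles`` (optional) to presence flags
    over whole tissues (e.g. grain/leaf/root).  A gene with fewer than three
    detected copies shows structural loss; detected copies with unequal
    profiles show expression divergence; a gene is conserved only when all
    three copies agree everywhere.
    """
    if not copies_detected:
        raise ValueError("a gene with zero detected copies is not assayed")
    labels: set[str] = set()
    if len(copies_detected) < 3:
        labels.add(STRUCTURAL_LOSS)
    grain = [tuple(grain_profiles[c]) for c in sorted(copies_detected) if c in grain_profiles]
    if grain and len(set(grain)) > 1:
        labels.add(DIVERGED_WITHIN)
    if tissue_profiles is not None:
        tissue = [
            tuple(tissue_profiles[c]) for c in sorted(copies_detected) if c in tissue_profiles
        ]
        if tissue and len(set(tissue)) > 1:
            labels.add(DIVERGED_BETWEEN)
    if not labels and len(copies_detected) == 3:
        labels.add(CONSERVED)
    return labels


def summarize_fates(
    n_assigned: int,
    n_structural_loss: int,
    n_expression_assayed: int,
    n_expr_loss_within: int,
    n_expr_loss_between: int,
    n_fully_conserved: int,
) -> FateSummary:
    return FateSummary(
        n_assigned=n_assigned,
        n_expression_assayed=n_expression_assayed,
        n_structural_loss=n_structural_loss,
        n_expr_loss_within=n_expr_loss_within,
        n_expr_loss_between=n_expr_loss_between,
        n_fully_conserved=n_fully_conserved,
    )


def truncate_percent(numerator: int, denominator: int) -> float:
    """Percent truncated (not rounded) to one decimal: 2600/6760 -> 38.4."""
    if denominator == 0:
        return 0.0
    return math.floor(1000.0 * numerator / denominator) / 10.0


def concerted_expression_rate(
    pairs: Sequence[tuple[Sequence[Sequence[bool]], Sequence[Sequence[bool]]]],
    include_paralogs: bool = False,
) -> tuple[int, float]:
    """Fraction of cross-species ortholog pairs with identical PAV profiles.

    Each element of ``pairs`` is (profiles_species_a, profiles_species_b)
    where the first profile of each side is the ortholog itself and any
    further profiles are its paralogs.  Without ``include_paralogs`` only the
    orthologs are compared; with it, a pair counts as concerted if any
    member (ortholog or paralog) of one side matches any of the other.
    Returns (count, percent truncated to one decimal).
    """
    concerted = 0
    for side_a, side_b in pairs:
        if not side_a or not side_b:
            continue
        a_profiles = [tuple(p) for p in (side_a if include_paralogs else side_a[:1])]
        b_profiles = [tuple(p) for p in (side_b if include_paralogs else side_b[:1])]
        if any(a == b for a in a_profiles for b in b_profiles):
            concerted += 1
    return concerted, truncate_percent(concerted, len(pairs))


def go_bias_test(
    counts: Sequence[GOCategoryCount],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-category 2x2 chi-square of (in-category vs rest) x (expressed set
    vs genome background); no multiplicity correction is applied.

    Categories with a zero margin are skipped with a warning.  Returns one
    row per tested category with the Pearson statistic, p-value, direction
    of the bias, and the ``biased`` flag (p < alpha).
    """
    grain_total = sum(c.observed for c in counts)
    genome_total = sum(c.background for c in counts)
    if genome_total <= 0:
        raise ValueError("background totals must be positive")
    rows = []
    for c in counts:
        table = np.array(
            [
                [c.observed, grain_total - c.observed],
                [c.background, genome_total - c.background],
            ],
            dtype=float,
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            warnings.warn(f"GO category {c.category!r} skipped: zero-margin table")
            continue
        stat, p = _pearson_chi2_2x2(table)
        obs_rate = c.observed / grain_total if grain_total else 0.0
        bg_rate = c.background / genome_total
        rows.append(
            {
                "category": c.category,
                "observed": c.observed,
                "background": c.background,
                "chi2": stat,
                "p_value": p,
                "direction": "enriched" if obs_rate > bg_rate else "depleted",
                "biased": p < alpha,
            }
        )
    return pd.DataFrame(rows)


def _pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = row @ col / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def network_wgd_enrichment(
    network_genes: Sequence[str],
    duplicate_pairs: Sequence[tuple[str, str]],
) -> tuple[int, int]:
    """WGD enrichment of a gene network.

    Each retained duplicate pair contributes one "extra" gene to the modern
    network; enrichment is 100 * n_pairs / network size (integer percent,
    half-up) and the reconstructed pre-WGD network has
    ``network size - n_pairs`` non-redundant genes.
    """
    genes = set(network_genes)
    if len(genes) != len(network_genes):
        raise ValueError("network gene list contains duplicates")
    for a, b in duplicate_pairs:
        if a not in genes or b not in genes:
            raise ValueError(f"duplicate pair ({a}, {b}) has a member outside the network")
    n_pairs = len(duplicate_pairs)
    enrichment = int(round_half_up(100.0 * n_pairs / len(network_genes)))
    return enrichment, len(network_genes) - n_pairs


def triplet_rate_percent(n_triplet: int, n_matched: int) -> int:
    """Integer percent (half-up) of matched genes with all three homoeologs."""
    if n_matched == 0:
        return 0
    return int(round_half_up(100.0 * n_triplet / n_matched))


def differential_expression(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    alpha: float = 0.05,
    var_quantiles: tuple[float, float] = (0.005, 0.995),
) -> pd.DataFrame:
    """Equal-variance two-group t-test per gene with Bonferroni control.

    ``matrix`` is genes x samples; ``groups`` labels each sample with one of
    exactly two group names (>= 2 samples each).  Genes whose pooled
    within-group variance falls outside ``var_quantiles`` of the variance
    distribution, and constant-zero genes, are excluded before testing.
    Bonferroni adjustment runs over the tested genes only; a gene is called
    differentially expressed iff the adjusted p-value is below ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    labels = pd.Series(list(groups), index=matrix.columns)
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError("exactly two group labels are required")
    a_cols = labels[labels == names[0]].index
    b_cols = labels[labels == names[1]].index
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least two samples")

    a = matrix[a_cols].to_numpy(float)
    b = matrix[b_cols].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    pooled_var = (
        (na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)
    ) / (na + nb - 2)

    constant_zero = (a == 0).all(axis=1) & (b == 0).all(axis=1)
    candidate = ~constant_zero
    if candidate.sum() == 0:
        raise ValueError("no testable genes")
    lo, hi = np.quantile(pooled_var[candidate], var_quantiles)
    tested = candidate & (pooled_var >= lo) & (pooled_var <= hi) & (pooled_var > 0)

    t_stat = np.full(len(matrix), np.nan)
    p_raw = np.full(len(matrix), np.nan)
    if tested.any():
        t_stat[tested], p_raw[tested] = stats.ttest_ind(
            a[tested], b[tested], axis=1, equal_var=True
        )
    p_adj = np.full(len(matrix), np.nan)
    if tested.any():
        p_adj[tested] = multipletests(p_raw[tested], method="bonferroni")[1]

    reason = np.where(
        constant_zero, "constant_zero", np.where(tested, "", "variance_extreme")
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "t": t_stat,
            "p_raw": p_raw,
            "p_bonferroni": p_adj,
            "differentially_expressed": np.where(tested, p_adj < alpha, False),
            "excluded_reason": reason,
        }
    ).set_index("gene_id")
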