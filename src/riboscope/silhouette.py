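"""Differential ribosome-silhouette statistic.

A silhouette is the per-position footprint-end count vector over one gene
body: it reflects the shape, not the depth, of ribosome coverage. Shallow
libraries leave many positions empty, and shared empty positions inflate
similarity, so each pair of silhouettes is first compressed by removing
coordinates with no reads in either; similarity is then Spearman rank
correlation (average ranks) on the compressed pair. A gene is compared
between two states by the median pairwise correlation within replicates
versus between states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats

from .genome import GenomeBundle
from .ingest import EndTrack

MIN_READS = 50
MIN_POSITIONS = 10


@dataclass
class Silhouette:
    gene_id: str
    counts: np.ndarray  # gene-local, 5'->3'
    metadata: dict | None = None


@dataclass
class SilhouetteComparison:
    gene_id: str
    median_within: float | None
    median_between: float | None
    n_positions_used: int
    eligible: bool
    flagged: bool


def gene_silhouettes(track: EndTrack, bundle: GenomeBundle, metadata: dict | None = None) -> dict[str, Silhouette]:
    return {
        g.gene_id: Silhouette(g.gene_id, track.gene_vector(g), metadata)
        for g in bundle.genes
    }


def _as_array(s) -> np.ndarray:
    return np.asarray(s.counts if isinstance(s, Silhouette) else s, dtype=float)


def compress_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Drop positions where both vectors are zero; keep single-zero positions."""
    a, b = _as_array(a), _as_array(b)
    if len(a) != len(b):
        raise ValueError("silhouettes must have equal length")
    keep = (a > 0) | (b > 0)
    return a[keep], b[keep]


def silhouette_similarity(a, b) -> float | None:
    """Spearman correlation of the compressed pair; None when undefined
    (fewer than 2 retained positions, or either vector constant)."""
    ca, cb = compress_pair(a, b)
    if len(ca) < 2 or np.all(ca == ca[0]) or np.all(cb == cb[0]):
        return None
    rho = stats.spearmanr(ca, cb).statistic
    return None if np.isnan(rho) else float(rho)


def eligibility(s, min_reads: int = MIN_READS, min_positions: int = MIN_POSITIONS) -> bool:
    """A profile qualifies with >= 50 mapped reads across >= 10 distinct positions."""
    counts = _as_array(s)
    return bool(counts.sum() >= min_reads and (counts > 0).sum() >= min_positions)


def compare_states(
    gene_id: str,
    states: dict[str, list],
    margin: float = 0.0,
    pool_within: bool = True,
    min_reads: int = MIN_READS,
    min_positions: int = MIN_POSITIONS,
) -> SilhouetteComparison:
    """Median within-state vs between-state silhouette similarity for one gene.

    ``states`` maps two state labels to their replicate silhouettes (>= 2
    each). Within-state pairs are pooled across both states by default
    (``pool_within=False`` restricts them to the first state). The gene is
    flagged differential when median_within - median_between > margin.
    """
    if len(states) != 2:
        raise ValueError("exactly two states required")
    (la, reps_a), (lb, reps_b) = states.items()
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise ValueError("at least two replicates per state required for the within-median")
    all_reps = list(reps_a) + list(reps_b)
    if not all(eligibility(r, min_reads, min_positions) for r in all_reps):
        return SilhouetteComparison(gene_id, None, None, 0, eligible=False, flagged=False)

    within_pairs = list(combinations(reps_a, 2))
    if pool_within:
        within_pairs += list(combinations(reps_b, 2))
    between_pairs = list(product(reps_a, reps_b))

    def median_of(pairs):
        # lower-median order statistic: equals the usual median for odd
        # counts and makes degenerate equalities (e.g. state B an exact copy
        # of state A) exact rather than interpolated for even counts
        vals = [silhouette_similarity(x, y) for x, y in pairs]
        if any(v is None for v in vals):
            return None
        return float(sorted(vals)[(len(vals) - 1) // 2])

    mw = median_of(within_pairs)
    mb = median_of(between_pairs)
    n_pos = min(
        len(compress_pair(x, y)[0]) for x, y in within_pairs + between_pairs
    )
    flagged = mw is not None and mb is not None and (mw - mb) > margin
    return SilhouetteComparison(gene_id, mw, mb, n_pos, eligible=True, flagged=flagged)


def compare_all(
    tracks_by_state: dict[str, list[EndTrack]],
    bundle: GenomeBundle,
    margin: float = 0.0,
    pool_within: bool = True,
):
    """Run compare_states for every gene from per-replicate end tracks.

    Returns a DataFrame: gene, median_within, median_between, n_positions,
    eligible, flagged.
    """
    import pandas as pd

    silhouettes = {
        state: [gene_silhouettes(t, bundle) for t in tracks]
        for state, tracks in tracks_by_state.items()
    }
    rows = []
    for g in bundle.genes:
        states = {
            state: [per_rep[g.gene_id] for per_rep in reps]
            for state, reps in silhouettes.items()
        }
        c = compare_states(g.gene_id, states, margin=margin, pool_within=pool_within)
        rows.append(
            {
                "gene": c.gene_id,
                "median_within": c.median_within,
                "median_between": c.median_between,
                "n_positions": c.n_positions_used,
                "eligible": c.eligible,
                "flagged": c.flagged,
            }
        )
    return pd.DataFrame(rows)
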