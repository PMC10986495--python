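"""Rend-seq transcription start site calling and leader classification.

Two per-position scores drive the caller, both over a 100 nt window each
side of the evaluated position n on a strand-oriented density track RNA(n):

    peak_density(n)  = RNA(n) / ( sum_{m=-100..100} RNA(n+m) / 200 )
    delta_density(n) = ( sum_{m=-100..0} RNA(n+m) + eps )
                       / ( sum_{m=1..100} RNA(n+m) + eps ),  eps = 0.001

with "upstream" meaning 5' on the feature's strand. Note the denominator of
peak_density divides a 201-term sum by 200, and the delta numerator includes
m=0; both follow the printed definitions exactly. At a true 5' end the
upstream window is empty, so delta_density is SMALL (the prose description
of delta as an upstream-over-downstream "increase" points the other way;
this implementation treats low delta as TSS-like — see docs/methods.md).

Candidates must first pass the prefilter (>= 5 reads at n and mean window
density >= 0.1), then peak_density >= min_peak and delta_density <=
max_delta; runs of passing positions closer than 5 nt collapse to their
maximal peak (ties to the 5'-most).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBundle
from .ingest import EndTrack

WINDOW = 100
DENOM = 200
EPS = 1e-3
PREFILTER_MIN_READS = 5
PREFILTER_MIN_DENSITY = 0.1


@dataclass
class TssCandidate:
    position: int
    strand: str
    contig: str
    peak_density: float
    delta_density: float
    gene: str | None
    leader_length: int | None
    status: str = "auto"


def _oriented(vec: np.ndarray, strand: str) -> np.ndarray:
    """View of the track in 5'->3' order for the given strand."""
    return vec if strand == "+" else vec[::-1]


def _window_sums(v: np.ndarray, w: int = WINDOW) -> np.ndarray:
    """sum_{m=-w..w} v[n+m] for every n with a full window; nan at edges."""
    c = np.concatenate(([0.0], np.cumsum(v)))
    out = np.full(len(v), np.nan)
    n = np.arange(w, len(v) - w)
    out[n] = c[n + w + 1] - c[n - w]
    return out


def _upstream_downstream_sums(v: np.ndarray, w: int = WINDOW):
    """(sum_{m=-w..0}, sum_{m=1..w}) per position in 5'->3' orientation."""
    c = np.concatenate(([0.0], np.cumsum(v)))
    up = np.full(len(v), np.nan)
    down = np.full(len(v), np.nan)
    n = np.arange(w, len(v) - w)
    up[n] = c[n + 1] - c[n - w]
    down[n] = c[n + w + 1] - c[n + 1]
    return up, down


def peak_density_profile(vec: np.ndarray, strand: str = "+") -> np.ndarray:
    v = _oriented(np.asarray(vec, dtype=float), strand)
    win = _window_sums(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        pd_ = np.where(win > 0, v / (win / DENOM), 0.0)
    pd_[np.isnan(win)] = np.nan  # truncated window: undefined
    return _oriented(pd_, strand)


def delta_density_profile(vec: np.ndarray, strand: str = "+", eps: float = EPS) -> np.ndarray:
    v = _oriented(np.asarray(vec, dtype=float), strand)
    up, down = _upstream_downstream_sums(v)
    dd = (up + eps) / (down + eps)
    return _oriented(dd, strand)


def peak_density(track: EndTrack, contig: str, strand: str, n: int) -> float:
    """Scalar peak density at one position (requires a full window)."""
    return float(peak_density_profile(track.vector(contig, strand), strand)[n])


def delta_density(track: EndTrack, contig: str, strand: str, n: int) -> float:
    return float(delta_density_profile(track.vector(contig, strand), strand)[n])


def prefilter_mask(vec: np.ndarray, strand: str = "+") -> np.ndarray:
    """Positions with >= 5 reads and mean density >= 0.1 over the 200 nt
    window; positions whose window is truncated by a contig edge fail."""
    v = np.asarray(vec, dtype=float)
    win = _window_sums(_oriented(v, strand))
    win = _oriented(win, strand)
    with np.errstate(invalid="ignore"):
        ok = (v >= PREFILTER_MIN_READS) & (win / (2 * WINDOW + 1) >= PREFILTER_MIN_DENSITY)
    ok[np.isnan(win)] = False
    return ok


def _collapse_runs(positions: np.ndarray, peaks: np.ndarray, strand: str,
                   merge_distance: int = 5) -> list[int]:
    """Within runs of candidates closer than merge_distance nt, keep the
    maximal-peak position; ties break to the 5'-most on the strand."""
    if not len(positions):
        return []
    order = np.argsort(positions)
    positions, peaks = positions[order], peaks[order]
    kept = []
    run = [0]
    for i in range(1, len(positions) + 1):
        if i < len(positions) and positions[i] - positions[i - 1] < merge_distance:
            run.append(i)
            continue
        rp, rk = positions[run], peaks[run]
        best = rk == rk.max()
        cand = rp[best]
        kept.append(int(cand.min() if strand == "+" else cand.max()))
        run = [i]
    return kept


def call_tss(
    track: EndTrack,
    bundle: GenomeBundle,
    min_peak: float = 10.0,
    max_delta: float = 0.5,
    merge_distance: int = 5,
    max_leader_span: int = 500,
    delta_track: EndTrack | None = None,
) -> pd.DataFrame:
    """Call TSS candidates and assign each to the nearest downstream start codon.

    ``delta_track`` lets delta_density run on a different density (e.g.
    RNA-seq coverage) than the peak score; by default both use ``track``.
    """
    dtrack = delta_track or track
    rows = []
    for contig, per_strand in track.counts.items():
        for strand in "+-":
            vec = per_strand[strand]
            ok = prefilter_mask(vec, strand)
            if not ok.any():
                continue
            pk = peak_density_profile(vec, strand)
            dd = delta_density_profile(dtrack.vector(contig, strand), strand)
            passing = ok & (pk >= min_peak) & (dd <= max_delta)
            pos = np.flatnonzero(passing)
            for p in _collapse_runs(pos, pk[pos], strand, merge_distance):
                gene, leader = _assign_gene(bundle, contig, strand, p, max_leader_span)
                rows.append(
                    {
                        "contig": contig,
                        "position": p,
                        "strand": strand,
                        "peak_density": float(pk[p]),
                        "delta_density": float(dd[p]),
                        "gene": gene,
                        "leader_length": leader,
                        "status": "auto",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["contig", "position", "strand", "peak_density", "delta_density",
                 "gene", "leader_length", "status"],
    ).sort_values(["contig", "position"]).reset_index(drop=True)


def _assign_gene(bundle: GenomeBundle, contig: str, strand: str, pos: int,
                 max_span: int) -> tuple[str | None, int | None]:
    best: tuple[int, str] | None = None
    for g in bundle.genes:
        if g.contig != contig or g.strand != strand:
            continue
        dist = g.atg_position - pos if strand == "+" else pos - g.atg_position
        if 0 <= dist <= max_span and (best is None or dist < best[0]):
            best = (dist, g.gene_id)
    if best is None:
        return None, None
    return best[1], best[0]


LEADERLESS_MAX = 4   # < 5 nt
LEADERED_MIN = 15    # >= 15 nt; 5-14 nt is the anomalous gap


def classify_leader(leader: int) -> str:
    if leader <= LEADERLESS_MAX:
        return "leaderless"
    if leader >= LEADERED_MIN:
        return "leadered"
    return "anomalous"


def leader_summary(candidates: pd.DataFrame) -> dict:
    """Leader-length histogram and class counts for assigned candidates."""
    assigned = candidates.dropna(subset=["gene"])
    leaders = assigned["leader_length"].astype(int)
    classes = leaders.map(classify_leader)
    hist = leaders.value_counts().sort_index().to_dict()
    counts = {c: int((classes == c).sum()) for c in ("leaderless", "leadered", "anomalous")}
    return {
        "histogram": hist,
        "class_counts": counts,
        "gap_empty": counts["anomalous"] == 0,
        "n_assigned": int(len(assigned)),
    }
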