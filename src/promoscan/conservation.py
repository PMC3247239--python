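"""Per-base conservation scores and the in-site vs. out-of-site rank test.

Conservation scores are per-base values in [0, 1] with the semantics
``1 - P(neutral evolution)`` from a phylogenetic rate model, so higher
means more conserved.  For each matrix family we pool, across the whole
promoter set, the scores of bases covered by predicted sites and the
scores of the remaining promoter bases, and apply a one-tailed
rank-sum (Mann–Whitney) test of whether in-site scores are higher.
Two variants are used: the whole site, and only the four core matrix
positions.  A family counts as significant when either variant passes.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats

EXACT_LIMIT = 10  # exact enumeration when both groups are this small


# ---------------------------------------------------------------------------
# score track preparation


def parse_wiggle(path):
    """Parse a wiggle (fixedStep/variableStep) or bedGraph file.

    Returns a DataFrame (chrom, start, end, value) in 0-based half-open
    coordinates.  Wiggle positions are 1-based per the format spec.
    """
    import pandas as pd

    rows = []
    mode = None
    chrom, start, step, span = None, 0, 1, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = line.split()[0]
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if mode == "fixedStep":
                    start = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                continue
            parts = line.split()
            if mode is None and len(parts) == 4:  # bedGraph
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            elif mode == "fixedStep":
                rows.append((chrom, start, start + span, float(parts[0])))
                start += step
            elif mode == "variableStep":
                pos = int(parts[0]) - 1
                rows.append((chrom, pos, pos + span, float(parts[1])))
            else:
                raise ValueError(f"cannot interpret line in {path}: {line!r}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def prepare_scores(raw_track, promoters, is_pvalue: bool = True):
    """Project a genome-coordinate score track into each promoter's frame.

    *raw_track* is a DataFrame (chrom, start, end, value) or a
    bedGraph/wiggle path.  Values are transformed to ``1 - value`` when
    *is_pvalue* (the raw track holds neutral-evolution P-values);
    otherwise taken as-is.  The per-promoter vectors follow the
    promoter orientation (reversed relative to the genome for - strand
    promoters); uncovered bases are NaN.  Tracks are stored on the
    promoters and returned as a dict; intervals outside every promoter
    are counted and logged.
    """
    import logging
    import pandas as pd

    if not isinstance(raw_track, pd.DataFrame):
        raw_track = parse_wiggle(raw_track)

    L = promoters.L
    tracks: dict[str, np.ndarray] = {}
    used = 0
    for p in promoters:
        if p.chrom is None or p.tss is None:
            raise ValueError(f"promoter {p.id} lacks genome coordinates")
        gstart = p.tss - L if p.strand == "+" else p.tss
        gend = gstart + L
        vec = np.full(L, np.nan)
        sub = raw_track[(raw_track["chrom"] == p.chrom)
                        & (raw_track["end"] > gstart) & (raw_track["start"] < gend)]
        for _, row in sub.iterrows():
            lo = max(int(row["start"]), gstart) - gstart
            hi = min(int(row["end"]), gend) - gstart
            val = 1.0 - row["value"] if is_pvalue else row["value"]
            vec[lo:hi] = val
            used += 1
        if p.strand == "-":
            vec = vec[::-1]
        tracks[p.id] = vec
        p.scores = vec
    dropped = len(raw_track) - used
    if dropped > 0:
        logging.getLogger(__name__).info(
            "%d score intervals fell outside the promoter set", dropped)
    return tracks


# ---------------------------------------------------------------------------
# rank-sum machinery


def rank_sum_greater(x, y) -> float:
    """One-tailed p-value that *x* is stochastically greater than *y*.

    Exact enumeration over rank assignments (with midranks for ties)
    when both groups have at most ``EXACT_LIMIT`` observations;
    otherwise the normal approximation with tie correction and
    continuity correction (scipy's Mann–Whitney U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= EXACT_LIMIT and y.size <= EXACT_LIMIT:
        return _exact_rank_sum_greater(x, y)
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum_greater(x, y) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n = x.size
    observed = ranks[:n].sum()
    total = 0
    at_least = 0
    for idx in combinations(range(pooled.size), n):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            at_least += 1
    return at_least / total


def wilcoxon_site_conservation(track, hits, region_length: int | None = None,
                               mode: str = "whole_site", pwms=None,
                               offset: int | None = None):
    """One-tailed rank-sum p for sites of one family being more conserved.

    Parameters
    ----------
    track : dict promoter_id -> per-base score vector (NaN = missing),
        aligned to the promoter frame (index 0 at TSS-relative *offset*).
    hits : predicted sites of the tested family (TSS-relative coords).
    region_length : promoter length; inferred from the tracks if None.
    mode : "whole_site" pools every base of each site; "core" pools only
        the four core matrix positions (requires *pwms*, a mapping of
        pwm id to :class:`~promoscan.pwm.Pwm`).
    offset : TSS-relative coordinate of track index 0 (default ``-L``).

    Returns
    -------
    (p, n_in, n_out); p is NaN when either pooled group is empty.
    """
    if mode not in ("whole_site", "core"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "core" and pwms is None:
        raise ValueError("core mode requires the pwms mapping for core positions")

    lengths = {len(v) for v in track.values()}
    if region_length is None:
        if len(lengths) != 1:
            raise ValueError("tracks have mixed lengths; pass region_length")
        region_length = lengths.pop()
    L = region_length
    if offset is None:
        offset = -L

    in_mask = {pid: np.zeros(L, dtype=bool) for pid in track}
    for h in hits:
        if h.promoter_id not in in_mask:
            continue
        mask = in_mask[h.promoter_id]
        if mode == "whole_site":
            lo, hi = h.start - offset, h.end - offset
            mask[max(lo, 0):min(hi, L)] = True
        else:
            pwm = pwms[h.pwm_id]
            for c in pwm.core_positions:
                # core positions index matrix columns; mirror on - strand
                pos = h.start + c if h.strand == "+" else h.end - 1 - c
                i = pos - offset
                if 0 <= i < L:
                    mask[i] = True

    inside, outside = [], []
    n_missing = 0
    for pid, vec in track.items():
        vec = np.asarray(vec, dtype=float)
        ok = np.isfinite(vec)
        n_missing += int((~ok).sum())
        m = in_mask[pid]
        inside.append(vec[m & ok])
        outside.append(vec[~m & ok])
    inside = np.concatenate(inside) if inside else np.zeros(0)
    outside = np.concatenate(outside) if outside else np.zeros(0)
    if inside.size == 0 or outside.size == 0:
        return float("nan"), int(inside.size), int(outside.size)
    p = rank_sum_greater(inside, outside)
    return p, int(inside.size), int(outside.size)
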