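"""Masking dominant motifs from promoters and every control dataset.

After a first round of analysis, sites of the dominant motif (here the
O/E family, at the relaxed scan stringency so that marginal sites are
removed too) and candidate TATA boxes close to the TSS are replaced by
``n`` in the promoter sequences *and*, at identical TSS-relative
positions, in the preceding control regions, every shuffled dataset,
and the conservation score tracks.  Masking rather than deleting
preserves coordinates, and masking all copies keeps the amount of
scannable sequence equal between real and control data so the
second-round tests remain calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from promoscan.promoters import Promoter, PromoterSet, merge_intervals

TATA_WINDOW = (-61, -10)  # inclusive TSS-relative window for TATA masking


@dataclass
class MaskSet:
    """Per-promoter sorted disjoint TSS-relative intervals to mask."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    provenance: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, promoter_id: str, start: int, end: int, tag: str = ""):
        self.provenance.setdefault(promoter_id, []).append((start, end, tag))
        merged = merge_intervals(
            self.intervals.get(promoter_id, []) + [(start, end)])
        self.intervals[promoter_id] = merged

    def masked_bases(self, promoter_id: str, lo: int, hi: int) -> int:
        """Number of masked bases within the TSS-relative window [lo, hi)."""
        return sum(max(0, min(e, hi) - max(s, lo))
                   for s, e in self.intervals.get(promoter_id, []))

    def index_arrays(self, offset: int, length: int) -> dict[str, np.ndarray]:
        """Masked positions as index arrays into a frame starting at *offset*."""
        out = {}
        for pid, ivs in self.intervals.items():
            idx = []
            for s, e in ivs:
                lo, hi = max(s - offset, 0), min(e - offset, length)
                if hi > lo:
                    idx.append(np.arange(lo, hi))
            if idx:
                out[pid] = np.concatenate(idx)
        return out

    def to_bed(self, path) -> None:
        """Serialize as BED with TSS-relative coordinates, provenance in name."""
        with open(path, "w") as fh:
            for pid in sorted(self.provenance):
                for s, e, tag in self.provenance[pid]:
                    fh.write(f"{pid}\t{s}\t{e}\t{tag}\t0\t+\n")


def build_mask(oe_hits_relaxed, tata_hits_opt=(), window=TATA_WINDOW) -> MaskSet:
    """Mask the full extent of relaxed-stringency dominant-motif sites plus
    TATA sites intersecting the TSS-proximal window.

    *window* is an inclusive TSS-relative interval; a TATA hit is masked
    when it overlaps any base of the window.  Overlapping mask
    intervals are merged.
    """
    mask = MaskSet()
    for h in oe_hits_relaxed:
        mask.add(h.promoter_id, h.start, h.end, f"{h.family_id}|opt-0.1")
    wlo, whi = window[0], window[1] + 1  # half-open
    for h in tata_hits_opt:
        if h.start < whi and h.end > wlo:
            mask.add(h.promoter_id, h.start, h.end, f"{h.family_id}|opt")
    return mask


def _mask_sequence(seq: str, ivs, offset: int) -> str:
    chars = list(seq)
    L = len(chars)
    for s, e in ivs:
        lo, hi = max(s - offset, 0), min(e - offset, L)
        for i in range(lo, hi):
            chars[i] = "n"
    return "".join(chars)


def mask_promoter_set(mask: MaskSet, promoters: PromoterSet) -> PromoterSet:
    """A copy of *promoters* with masked positions set to 'n' (preceding
    regions masked at the equivalent TSS-relative positions)."""
    out = []
    for p in promoters:
        ivs = mask.intervals.get(p.id, [])
        seq = _mask_sequence(p.sequence, ivs, promoters.offset)
        prec = p.preceding
        if prec is not None:
            # the preceding region is masked at the same within-sequence
            # positions: interval [a, b) maps to [a - L, b - L)
            shifted = [(s - promoters.L, e - promoters.L) for s, e in ivs]
            prec = _mask_sequence(prec, shifted, promoters.offset - promoters.L)
        out.append(Promoter(id=p.id, sequence=seq, chrom=p.chrom, tss=p.tss,
                            strand=p.strand, preceding=prec, scores=p.scores))
    return PromoterSet(out, offset=promoters.offset)


def apply_mask_everywhere(mask: MaskSet, promoters: PromoterSet,
                          preceding_regions: PromoterSet | None = None,
                          shuffled_sets=None, score_tracks=None):
    """Mask identical TSS-relative positions in every dataset kind.

    Returns ``(masked_promoters, masked_preceding, masked_shuffled,
    masked_tracks)``; entries are None when the corresponding input is.
    Sequences get 'n' at masked positions; score tracks get NaN.  All
    inputs must share the TSS-relative frame of *promoters* (the
    preceding regions sit at offset ``-2L`` and are masked at the
    equivalent shifted positions).
    """
    masked_prom = mask_promoter_set(mask, promoters)

    masked_prec = None
    if preceding_regions is not None:
        if preceding_regions.L != promoters.L:
            raise ValueError("preceding regions frame mismatch: lengths differ")
        shifted = MaskSet()
        for pid, ivs in mask.intervals.items():
            for s, e in ivs:
                shifted.add(pid, s - promoters.L, e - promoters.L, "shifted")
        masked_prec = mask_promoter_set(shifted, preceding_regions)

    masked_shuffled = None
    if shuffled_sets is not None:
        masked_shuffled = [mask_promoter_set(mask, ds) for ds in shuffled_sets]

    masked_tracks = None
    if score_tracks is not None:
        masked_tracks = {}
        idx = mask.index_arrays(promoters.offset, promoters.L)
        for pid, vec in score_tracks.items():
            v = np.array(vec, dtype=float, copy=True)
            if pid in idx:
                v[idx[pid]] = np.nan
            masked_tracks[pid] = v
    return masked_prom, masked_prec, masked_shuffled, masked_tracks
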