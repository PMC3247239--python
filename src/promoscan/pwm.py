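"""Position weight matrices and MatInspector-style promoter scanning.

A PWM match is scored with the Quandt-style matrix similarity score

    mss(window) = sum_i C_i * f(i, b_i) / sum_i C_i * max_b f(i, b)

where ``f(i, b)`` is the pseudocounted column frequency of base ``b`` at
matrix position ``i`` and ``C_i`` is the per-position information weight

    C_i = (100 / ln 4) * sum_b f(i, b) * ln(4 * f(i, b)),

clipped at zero.  A window is reported as a site only if the similarity
computed over the four most informative ("core") positions is at least
the core gate (0.75 by default) *and* the full-matrix similarity reaches
the scan threshold.  Two stringencies are used throughout the package:
the per-matrix optimized threshold ("opt", calibrated to a low match
rate on background sequence) and a relaxed threshold 0.1 units lower
("opt-0.1", floored at 0.5).

Both strands are always scanned; lowercase and ``N`` bases are treated
as masked and contribute zero frequency to any window overlapping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CORE_GATE = 0.75
DEFAULT_OPT_THRESHOLD = 0.85
RELAXED_DELTA = 0.1
RELAXED_FLOOR = 0.5
PSEUDOCOUNT = 0.01

_BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
for _b in "acgtnN":  # lowercase (soft-masked) and N score zero
    _ENCODE[ord(_b)] = 4

_TWO_LETTER_IUPAC = {
    frozenset("AC"): "m", frozenset("AG"): "r", frozenset("AT"): "w",
    frozenset("CG"): "s", frozenset("CT"): "y", frozenset("GT"): "k",
}


class PwmFormatError(ValueError):
    """Raised when a PWM library file cannot be parsed."""


def encode_sequence(seq: str, promoter_id: str = "?") -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, masked -> 4).

    Raises ``ValueError`` naming *promoter_id* if the sequence contains
    characters other than A/C/G/T/N in either case.
    """
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({c for c in seq if _ENCODE[ord(c)] == 255})
        raise ValueError(
            f"non-nucleotide characters {bad!r} in sequence of promoter {promoter_id!r}"
        )
    return codes


@dataclass
class Pwm:
    """A position frequency matrix with information weights and a threshold.

    ``counts`` is a 4 x L non-negative matrix (rows A, C, G, T).  Derived
    fields (``frequencies``, ``info``, ``core_positions``, ``consensus``)
    are computed by :meth:`from_counts`.
    """

    id: str
    family_id: str
    counts: np.ndarray
    frequencies: np.ndarray
    info: np.ndarray
    core_positions: tuple[int, ...]
    opt_threshold: float = DEFAULT_OPT_THRESHOLD
    consensus: str = ""

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def relaxed_threshold(self) -> float:
        return max(self.opt_threshold - RELAXED_DELTA, RELAXED_FLOOR)

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts,
        family_id: str | None = None,
        opt_threshold: float = DEFAULT_OPT_THRESHOLD,
        pseudocount: float = PSEUDOCOUNT,
        n_core: int = 4,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise PwmFormatError(f"matrix {id!r}: expected 4 x L counts, got shape {counts.shape}")
        if (counts < 0).any() or not np.isfinite(counts).all():
            raise PwmFormatError(f"matrix {id!r}: counts must be finite and non-negative")
        freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=0, keepdims=True)
        info = _information_weights(freq)
        L = counts.shape[1]
        k = min(n_core, L)
        # k highest-information positions, leftmost first on ties
        core = tuple(sorted(np.argsort(-info, kind="stable")[:k].tolist()))
        cons = _consensus(freq)
        if family_id is None:
            family_id = family_from_id(id)
        return cls(id=id, family_id=family_id, counts=counts, frequencies=freq,
                   info=info, core_positions=core, opt_threshold=opt_threshold,
                   consensus=cons)

    def threshold(self, mode: str) -> float:
        if mode == "opt":
            return self.opt_threshold
        if mode in ("opt-0.1", "relaxed"):
            return self.relaxed_threshold
        raise ValueError(f"unknown threshold mode {mode!r} (expected 'opt' or 'opt-0.1')")

    def reverse_complement(self) -> "Pwm":
        rc_counts = self.counts[::-1, ::-1]
        pwm = Pwm.from_counts(self.id, rc_counts, family_id=self.family_id,
                              opt_threshold=self.opt_threshold)
        return pwm


@dataclass
class PwmFamily:
    """A group of PWMs representing the same or similar factors."""

    id: str
    member_ids: list[str]
    description: str = ""

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError(f"family {self.id!r} has no members")


@dataclass(frozen=True)
class SiteHit:
    """One predicted binding site, in TSS-relative coordinates.

    ``start``/``end`` form a 0-based half-open interval with the TSS at 0
    and upstream positions negative; ``strand`` is relative to the
    promoter orientation.
    """

    promoter_id: str
    start: int
    end: int
    strand: str
    pwm_id: str
    family_id: str
    score: float


def _information_weights(freq: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = freq * np.log(4.0 * freq)
        term[freq == 0] = 0.0
    ci = (100.0 / math.log(4.0)) * term.sum(axis=0)
    return np.clip(ci, 0.0, None)


def _consensus(freq: np.ndarray) -> str:
    out = []
    for col in freq.T:
        order = np.argsort(-col, kind="stable")
        if col[order[0]] >= 0.5:
            out.append(_BASES[order[0]])
        elif col[order[0]] + col[order[1]] >= 0.75:
            pair = frozenset(_BASES[order[0]] + _BASES[order[1]])
            out.append(_TWO_LETTER_IUPAC[pair])
        else:
            out.append("n")
    return "".join(out)


def family_from_id(pwm_id: str) -> str:
    """Family tag derived from a matrix id: the part before the last '_'.

    ``V$NOLF_01`` -> ``V$NOLF``; ids without an underscore are their own
    family.
    """
    if "_" in pwm_id:
        return pwm_id.rsplit("_", 1)[0]
    return pwm_id


# ---------------------------------------------------------------------------
# loading


def load_pwms(path, format: str = "transfac", family_map=None):
    """Load a PWM library; returns ``(pwms, families)``.

    Parameters
    ----------
    path : str or Path
        TRANSFAC flat file (``ID``/``P0`` records) or JASPAR ``.pfm``.
    format : {"transfac", "jaspar"}
    family_map : str, Path or dict, optional
        TSV with columns (matrix_id, family_id, description), or a dict
        mapping matrix id to family id.  When absent, the family is
        derived from the id prefix before the last underscore.
    """
    from Bio import motifs as bio_motifs

    fam_of, fam_desc = {}, {}
    if family_map is not None:
        if isinstance(family_map, dict):
            fam_of = dict(family_map)
        else:
            with open(family_map) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    parts = line.rstrip("\n").split("\t")
                    fam_of[parts[0]] = parts[1]
                    if len(parts) > 2:
                        fam_desc[parts[1]] = parts[2]

    fmt = format.lower()
    if fmt not in ("transfac", "jaspar"):
        raise ValueError(f"unknown PWM format {format!r}")
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC" if fmt == "transfac" else "jaspar")
            records = list(records)
        except Exception as exc:  # surface parse problems as format errors
            raise PwmFormatError(f"cannot parse {path} as {format}: {exc}") from exc

    pwms = []
    for rec in records:
        if fmt == "transfac":
            mid = rec.get("ID") or rec.get("AC") or rec.name
        else:
            mid = rec.matrix_id or rec.name
        counts = np.array([rec.counts[b] for b in _BASES], dtype=float)
        pwms.append(Pwm.from_counts(str(mid), counts, family_id=fam_of.get(str(mid))))

    families: dict[str, PwmFamily] = {}
    for pwm in pwms:
        if pwm.family_id in families:
            families[pwm.family_id].member_ids.append(pwm.id)
        else:
            families[pwm.family_id] = PwmFamily(
                id=pwm.family_id, member_ids=[pwm.id],
                description=fam_desc.get(pwm.family_id, ""))
    return pwms, list(families.values())


def write_pwms_transfac(pwms, path) -> None:
    """Write matrices as a TRANSFAC flat file (round-trips through
    :func:`load_pwms`)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID  {pwm.id}\n")
            fh.write("P0      A      C      G      T\n")
            for i in range(pwm.length):
                a, c, g, t = pwm.counts[:, i]
                cons = pwm.consensus[i].upper() if pwm.consensus else "N"
                fh.write(f"{i + 1:02d}      {a:g}      {c:g}      {g:g}"
                         f"      {t:g}      {cons}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# scanning


class _Profile:
    """Precomputed scoring arrays for one PWM on one strand."""

    __slots__ = ("pwm", "strand", "weights5", "denom", "core_cols", "core_denom", "length")

    def __init__(self, pwm: Pwm, strand: str):
        src = pwm if strand == "+" else pwm.reverse_complement()
        L = src.length
        w = src.info
        f = src.frequencies
        # weights5[b, i] = C_i * f(i, b); masked code 4 contributes 0
        w5 = np.zeros((5, L))
        w5[:4] = w * f
        self.pwm = pwm
        self.strand = strand
        self.length = L
        self.weights5 = w5
        denom = float((w * f.max(axis=0)).sum())
        self.denom = denom if denom > 0 else 1.0
        core = np.array(src.core_positions, dtype=int)
        self.core_cols = core
        cden = float((w[core] * f[:, core].max(axis=0)).sum())
        self.core_denom = cden if cden > 0 else 1.0

    def window_scores(self, codes: np.ndarray):
        """(core_similarity, matrix_similarity) for every window of *codes*."""
        L = self.length
        n = codes.size - L + 1
        if n <= 0:
            z = np.zeros(0)
            return z, z
        v = self.weights5[codes]  # (N, L) gather
        d = np.lib.stride_tricks.as_strided(
            v, shape=(n, L), strides=(v.strides[0], v.strides[0] + v.strides[1]))
        mss = d.sum(axis=1) / self.denom
        core = d[:, self.core_cols].sum(axis=1) / self.core_denom
        return core, mss

    def scan(self, codes: np.ndarray, threshold: float, core_gate: float = CORE_GATE):
        """Window starts and matrix similarities of gated, passing windows.

        Applies the core gate first (cheap: only the core columns are
        scored for every window), then evaluates the full matrix
        similarity only at core-passing windows.
        """
        L = self.length
        n = codes.size - L + 1
        if n <= 0:
            return np.zeros(0, dtype=np.intp), np.zeros(0)
        core = np.zeros(n)
        w5 = self.weights5
        for c in self.core_cols:
            core += w5[codes[c:c + n], c]
        cand = np.flatnonzero(core >= core_gate * self.core_denom)
        if cand.size == 0:
            return cand, np.zeros(0)
        num = np.zeros(cand.size)
        for i in range(L):
            num += w5[codes[cand + i], i]
        mss = num / self.denom
        keep = mss >= threshold
        return cand[keep], mss[keep]


def _profiles(pwm: Pwm) -> tuple[_Profile, _Profile]:
    return _Profile(pwm, "+"), _Profile(pwm, "-")


def _sequences_of(seqs):
    """Normalize the promoter-set argument to (ids, sequences, offset)."""
    if hasattr(seqs, "promoters"):  # PromoterSet
        ids = [p.id for p in seqs.promoters]
        strings = [p.sequence for p in seqs.promoters]
        return ids, strings, seqs.offset
    if isinstance(seqs, dict):
        ids = list(seqs)
        return ids, [seqs[i] for i in ids], None
    raise TypeError("seqs must be a PromoterSet or a mapping id -> sequence")


def scan_sequences(seqs, pwms, threshold_mode: str = "opt",
                   core_gate: float = CORE_GATE, offset: int | None = None) -> list[SiteHit]:
    """Scan promoter sequences with PWMs on both strands.

    *seqs* is a :class:`~promoscan.promoters.PromoterSet` or a mapping of
    id to sequence.  Coordinates in the returned hits are TSS-relative
    when the promoter set carries an offset (sequence position 0 maps to
    relative coordinate ``offset``); for a plain mapping the offset
    defaults to 0 unless given.
    """
    ids, strings, set_offset = _sequences_of(seqs)
    if offset is None:
        offset = set_offset if set_offset is not None else 0
    if isinstance(pwms, Pwm):
        pwms = [pwms]
    hits: list[SiteHit] = []
    profiles = [(_Profile(p, "+"), _Profile(p, "-")) for p in pwms]
    for pid, seq in zip(ids, strings):
        codes = encode_sequence(seq, pid)
        for pwm, (fwd, rev) in zip(pwms, profiles):
            t = pwm.threshold(threshold_mode)
            for prof in (fwd, rev):
                starts, scores = prof.scan(codes, t, core_gate)
                for j, s in zip(starts, scores):
                    hits.append(SiteHit(
                        promoter_id=pid,
                        start=int(j) + offset,
                        end=int(j) + offset + pwm.length,
                        strand=prof.strand,
                        pwm_id=pwm.id,
                        family_id=pwm.family_id,
                        score=float(s),
                    ))
    hits.sort(key=lambda h: (h.promoter_id, h.family_id, h.start, h.end, h.strand))
    return hits


def calibrate_thresholds(pwm: Pwm, background_seqs, target_rate: float = 0.3,
                         grid=(0.60, 1.00, 0.01)) -> float:
    """Smallest grid threshold with at most *target_rate* matches per kb.

    Scans the background on both strands (core gate applied) and picks
    the smallest threshold ``t`` on a 0.01 grid in [0.60, 1.00] such
    that the match rate is at most *target_rate* per kb; returns 1.00 if
    no grid value attains the rate.  The relaxed threshold used
    elsewhere is ``opt - 0.1`` floored at 0.5.
    """
    if isinstance(background_seqs, str):
        background_seqs = [background_seqs]
    ids, strings, _ = (None, background_seqs, None) if isinstance(background_seqs, list) \
        else _sequences_of(background_seqs)
    total = sum(len(s) for s in strings)
    if total == 0:
        raise ValueError("empty background: supply sequences or use the fixed default "
                         f"opt threshold {DEFAULT_OPT_THRESHOLD}")
    if total < 10_000:
        import warnings
        warnings.warn(f"background is only {total} bp (< 10 kb); calibration may be noisy")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")

    passing_scores = []
    for i, seq in enumerate(strings):
        codes = encode_sequence(seq, f"background[{i}]")
        for prof in _profiles(pwm):
            _, mss = prof.scan(codes, 0.0, CORE_GATE)
            passing_scores.append(mss)
    scores = np.sort(np.concatenate(passing_scores)) if passing_scores else np.zeros(0)

    lo, hi, step = grid
    n_steps = int(round((hi - lo) / step))
    max_hits = target_rate * total / 1000.0
    for k in range(n_steps + 1):
        t = round(lo + k * step, 10)
        n_hits = scores.size - np.searchsorted(scores, t, side="left")
        if n_hits <= max_hits:
            return float(t)
    return float(hi)


# ---------------------------------------------------------------------------
# family pruning


def family_prune(hits: list[SiteHit]) -> list[SiteHit]:
    """Keep only the highest-scoring hit per family in any overlapping region.

    Within each promoter and family, hits overlapping transitively (on
    either strand) form a group; the best-scoring hit of each group is
    retained.  Ties break toward the longer matrix, then the leftmost
    start, then the + strand.
    """
    from collections import defaultdict

    grouped: dict[tuple[str, str], list[SiteHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.promoter_id, h.family_id)].append(h)

    kept: list[SiteHit] = []
    for key in grouped:
        block = sorted(grouped[key], key=lambda h: (h.start, h.end))
        group: list[SiteHit] = []
        group_end = None
        for h in block:
            if group and h.start >= group_end:
                kept.append(_best_hit(group))
                group = []
                group_end = None
            group.append(h)
            group_end = h.end if group_end is None else max(group_end, h.end)
        if group:
            kept.append(_best_hit(group))
    kept.sort(key=lambda h: (h.promoter_id, h.family_id, h.start, h.end, h.strand))
    return kept


def _best_hit(group: list[SiteHit]) -> SiteHit:
    return max(group, key=lambda h: (h.score, h.end - h.start, -h.start, h.strand == "+"))


# ---------------------------------------------------------------------------
# output


def hits_to_bed(hits: list[SiteHit], path) -> None:
    """Write hits as BED6 with TSS-relative coordinates in the name field."""
    with open(path, "w") as fh:
        for h in hits:
            name = f"{h.pwm_id}|{h.family_id}|{h.start}:{h.end}"
            fh.write(f"{h.promoter_id}\t{h.start}\t{h.end}\t{name}\t"
                     f"{int(round(h.score * 1000))}\t{h.strand}\n")


def hits_to_tsv(hits: list[SiteHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tstart\tend\tstrand\tpwm_id\tfamily_id\tscore\n")
        for h in hits:
            fh.write(f"{h.promoter_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                     f"{h.pwm_id}\t{h.family_id}\t{h.score:.6f}\n")
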