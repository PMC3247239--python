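"""Enrichment statistics: binomial test vs. the preceding region and an
empirical null from dinucleotide-preserving shuffles.

The binomial test asks whether predicted sites are more numerous in the
promoter region than in the immediately preceding region of equal
length, under the null that a site is equally likely to fall in either
(``p = P(X >= k), X ~ Binomial(k + k_control, 1/2)``, exact tail sum in
log space so p-values down to ~1e-300 are representable).

The empirical null shuffles every promoter sequence while preserving
its exact mono- and dinucleotide composition (Altschul–Erickson
Eulerian-path shuffle), rescans, and asks in what fraction of B
shuffled datasets the per-family site count reaches the observed one.
Multiple testing across families is controlled by Bonferroni.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from promoscan.pwm import CORE_GATE, Pwm, _Profile, encode_sequence

DEFAULT_B = 10_000


@dataclass
class EnrichmentRow:
    """Per-family enrichment result: the machine twin of a report row."""

    family_id: str
    n_promoter: int
    n_promoters_with_site: int
    n_control_region: int
    fold_vs_region: float
    p_binomial: float
    shuffle_mean: float
    fold_vs_shuffle: float
    p_empirical: float
    B: int

    @property
    def p_empirical_label(self) -> str:
        return format_empirical_p(self.p_empirical, self.B)


def format_empirical_p(p: float, B: int) -> str:
    """Render an empirical p-value, printing ``<1/B`` when no shuffle reached
    the observed count."""
    return f"<{1.0 / B:g}" if p == 0 else f"{p:g}"


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle


def dinuc_shuffle(seq: str, seed) -> str:
    """Shuffle *seq* preserving its exact mono- and dinucleotide composition.

    Altschul–Erickson Eulerian-path shuffle: the first and last
    characters are fixed and the multiset of adjacent pairs is
    preserved exactly.  Runs of masked bases (``n``/``N`` or lowercase)
    stay in place; the unmasked segments between them are shuffled
    independently.  Deterministic given *seed* (an int, or a
    ``random.Random``).  Sequences shorter than 2 are returned
    unchanged.
    """
    if len(seq) < 2:
        return seq
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    codes = encode_sequence(seq, "?").copy()
    shuffled = _shuffle_codes(codes, rng)
    out = list(seq)
    bases = "ACGT"
    for i, c in enumerate(shuffled):
        if c < 4:
            out[i] = bases[c]  # masked positions keep their original character
    return "".join(out)


def _shuffle_codes(codes: np.ndarray, rng: random.Random) -> np.ndarray:
    """Shuffle encoded sequence in place-respecting segments; returns a copy."""
    out = codes.copy()
    n = out.size
    i = 0
    while i < n:
        if out[i] == 4:
            i += 1
            continue
        j = i
        while j < n and out[j] != 4:
            j += 1
        if j - i >= 3:
            out[i:j] = _ae_shuffle(out[i:j].tolist(), rng)
        i = j
    return out


def _ae_shuffle(seg: list[int], rng: random.Random) -> list[int]:
    """Altschul–Erickson shuffle of one unmasked segment (list of 0..3)."""
    n = len(seg)
    last = seg[-1]
    succ: list[list[int]] = [[] for _ in range(4)]
    for a, b in zip(seg, seg[1:]):
        succ[a].append(b)
    verts = [v for v in range(4) if succ[v] and v != last]

    # pick a random "last edge" for every non-terminal vertex until the
    # chosen edges form an arborescence into the terminal vertex
    randrange = rng.randrange
    while True:
        last_edge = [-1, -1, -1, -1]
        for v in verts:
            ev = succ[v]
            last_edge[v] = ev[randrange(len(ev))]
        ok = True
        for v in verts:
            u, steps = v, 0
            while u != last:
                u = last_edge[u]
                steps += 1
                if u < 0 or steps > 4:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break

    order: list[list[int]] = [[], [], [], []]
    for v in range(4):
        if not succ[v]:
            continue
        pool = list(succ[v])
        if last_edge[v] >= 0:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if last_edge[v] >= 0:
            pool.append(last_edge[v])
        order[v] = pool

    ptr = [0, 0, 0, 0]
    cur = seg[0]
    out = [cur]
    for _ in range(n - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return out


# ---------------------------------------------------------------------------
# tests


def binomial_enrichment(n_promoter: int, n_control: int) -> tuple[float, float]:
    """One-tailed binomial test of promoter vs. control-region site counts.

    Under the null a site falls in either 200-bp region with equal
    probability; ``p = P(X >= n_promoter)`` for ``X ~ Binomial(n, 1/2)``
    with ``n = n_promoter + n_control``, computed as an exact tail sum
    in log space.  Returns ``(fold, p)``; fold is ``inf`` when the
    control count is zero.  Raises ``ValueError`` when both counts are
    zero (such rows are skipped).
    """
    k, m = int(n_promoter), int(n_control)
    if k < 0 or m < 0:
        raise ValueError("counts must be non-negative")
    n = k + m
    if n == 0:
        raise ValueError("both counts are zero; row should be skipped")
    i = np.arange(k, n + 1)
    log_terms = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1) - n * np.log(2.0)
    p = float(np.exp(logsumexp(log_terms)))
    p = min(p, 1.0)
    fold = k / m if m > 0 else float("inf")
    return fold, p


def shuffle_null_test(observed: int, shuffled_counts,
                      strict: bool = False) -> tuple[float, float]:
    """Empirical enrichment against shuffled-sequence site counts.

    ``p = #(shuffled >= observed) / B`` (``>`` instead of ``>=`` when
    *strict*); a p of exactly 0 is conventionally reported as "<1/B".
    Fold is observed over the mean shuffled count (``inf`` when the
    mean is zero and the observation positive).  Requires B >= 100.
    """
    counts = np.asarray(list(shuffled_counts), dtype=float)
    B = counts.size
    if B < 100:
        raise ValueError(f"need at least 100 shuffle replicates, got {B}")
    hits = (counts > observed) if strict else (counts >= observed)
    p = float(hits.sum()) / B
    mean = float(counts.mean())
    if mean > 0:
        fold = observed / mean
    else:
        fold = float("inf") if observed > 0 else float("nan")
    return fold, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# fast bulk scanning for the shuffle null


class FamilyCounter:
    """Counts pruned per-family sites across many sequences at once.

    Sequences are concatenated with masked separators and each
    PWM/strand profile is scanned once over the concatenation; windows
    spanning two sequences are discarded.  Per promoter and family,
    transitively overlapping hits count once (matching
    :func:`promoscan.pwm.family_prune` group counting).
    """

    def __init__(self, pwms: list[Pwm], threshold_mode: str = "opt",
                 core_gate: float = CORE_GATE):
        self.pwms = list(pwms)
        self.mode = threshold_mode
        self.core_gate = core_gate
        self.family_ids = sorted({p.family_id for p in self.pwms})
        self._fam_index = {f: i for i, f in enumerate(self.family_ids)}
        self._scanners = []
        for pwm in self.pwms:
            t = pwm.threshold(threshold_mode)
            fam = self._fam_index[pwm.family_id]
            for strand in "+-":
                self._scanners.append((_Profile(pwm, strand), t, fam, pwm.length))
        self._max_len = max(p.length for p in self.pwms)

    def concat(self, codes_list: list[np.ndarray]):
        """Concatenate encoded sequences with masked separators.

        Returns ``(codes, seq_starts, seq_index_of_position)``.
        """
        sep = self._max_len
        total = sum(c.size for c in codes_list) + sep * (len(codes_list) - 1)
        codes = np.full(total, 4, dtype=np.uint8)
        starts = np.empty(len(codes_list), dtype=np.intp)
        pos = 0
        for i, c in enumerate(codes_list):
            starts[i] = pos
            codes[pos:pos + c.size] = c
            pos += c.size + sep
        return codes, starts

    def hit_arrays(self, codes_list: list[np.ndarray]):
        """Raw (unpruned) hits: arrays (seq_idx, start, end, family_idx, score)."""
        codes, starts = self.concat(codes_list)
        lengths = np.array([c.size for c in codes_list], dtype=np.intp)
        seq_idx_all, s_all, e_all, f_all, sc_all = [], [], [], [], []
        for prof, t, fam, m in self._scanners:
            w, scores = prof.scan(codes, t, self.core_gate)
            if w.size == 0:
                continue
            si = np.searchsorted(starts, w, side="right") - 1
            rel = w - starts[si]
            ok = rel + m <= lengths[si]  # drop separator-spanning windows
            if not ok.any():
                continue
            seq_idx_all.append(si[ok])
            s_all.append(rel[ok])
            e_all.append(rel[ok] + m)
            f_all.append(np.full(ok.sum(), fam, dtype=np.intp))
            sc_all.append(scores[ok])
        if not seq_idx_all:
            z = np.zeros(0, dtype=np.intp)
            return z, z, z, z, np.zeros(0)
        return (np.concatenate(seq_idx_all), np.concatenate(s_all),
                np.concatenate(e_all), np.concatenate(f_all),
                np.concatenate(sc_all))

    def family_counts(self, codes_list: list[np.ndarray]):
        """Pruned site counts and promoters-with-site counts per family.

        Returns ``(counts, promoters_with_site)`` as int arrays indexed
        like ``family_ids``.
        """
        si, s, e, f, _ = self.hit_arrays(codes_list)
        nfam = len(self.family_ids)
        if si.size == 0:
            return (np.zeros(nfam, dtype=np.int64), np.zeros(nfam, dtype=np.int64))
        order = np.lexsort((e, s, si, f))
        si, s, e, f = si[order], s[order], e[order], f[order]
        # one (family, promoter) block per distinct pair; within a block,
        # sorted by start, a hit opens a new overlap group iff its start
        # reaches the running max end of all previous hits in the block
        block_start = np.empty(si.size, dtype=bool)
        block_start[0] = True
        block_start[1:] = (f[1:] != f[:-1]) | (si[1:] != si[:-1])
        bid = np.cumsum(block_start) - 1
        big = int(e.max()) + 1
        keyed = bid.astype(np.int64) * big + e
        run_max = np.maximum.accumulate(keyed) - bid * big
        new_group = block_start.copy()
        new_group[1:] |= s[1:] >= run_max[:-1]
        counts = np.bincount(f[new_group], minlength=nfam).astype(np.int64)
        with_site = np.bincount(f[block_start], minlength=nfam).astype(np.int64)
        return counts, with_site


def shuffled_family_counts(promoter_set, pwms, B: int, seed: int,
                           threshold_mode: str = "opt",
                           mask_indices: dict | None = None) -> np.ndarray:
    """Per-family pruned site counts over B dinucleotide-shuffled datasets.

    Each promoter sequence is shuffled with a seed derived from
    ``(seed, promoter id, replicate)`` so any replicate is reproducible
    in isolation.  When *mask_indices* maps promoter ids to index
    arrays, the shuffle is performed on the unmasked sequence and the
    masked positions are re-masked afterwards (shuffle-then-mask, so
    the same amount of scannable sequence is kept as in the masked real
    data).

    Returns an int array of shape ``(B, n_families)`` in the family
    order of ``FamilyCounter(pwms).family_ids``.
    """
    counter = FamilyCounter(pwms, threshold_mode)
    ids = promoter_set.ids
    base_codes = [encode_sequence(p.sequence, p.id) for p in promoter_set]
    out = np.zeros((B, len(counter.family_ids)), dtype=np.int64)
    for rep in range(B):
        rep_codes = []
        for pid, codes in zip(ids, base_codes):
            rng = random.Random(f"{seed}:{pid}:{rep}")
            shuf = _shuffle_codes(codes, rng)
            if mask_indices and pid in mask_indices:
                shuf[mask_indices[pid]] = 4
            rep_codes.append(shuf)
        out[rep], _ = counter.family_counts(rep_codes)
    return out


def observed_family_counts(promoter_set, pwms, threshold_mode: str = "opt",
                           mask_indices: dict | None = None):
    """Pruned per-family counts on the real sequences (and promoters with
    a site), in ``FamilyCounter.family_ids`` order."""
    counter = FamilyCounter(pwms, threshold_mode)
    codes_list = []
    for p in promoter_set:
        codes = encode_sequence(p.sequence, p.id).copy()
        if mask_indices and p.id in mask_indices:
            codes[mask_indices[p.id]] = 4
        codes_list.append(codes)
    counts, with_site = counter.family_counts(codes_list)
    return counter.family_ids, counts, with_site
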