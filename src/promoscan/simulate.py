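"""Synthetic promoter datasets with the statistical structure the
analysis assumes.

The generator emulates the measured properties of AT-rich promoter
sets of large gene families: ~36.4% GC background drawn from a
first-order (dinucleotide) Markov chain, planted PWM instances with a
TSS-proximal positional bias (about 1.4 sites per 200-bp promoter for
the dominant motif), elevated conservation scores inside planted
sites, per-species site sets with positional turnover along a species
tree, and recent-duplicate sequence pairs.  Every stage of the
pipeline, and the end-to-end analysis, can therefore be exercised with
no external data; all randomness flows from one seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from promoscan.promoters import Promoter, PromoterSet, reverse_complement
from promoscan.pwm import Pwm, SiteHit
from promoscan.phylo import PromoterAlignment

_BASES = "ACGT"

#: species tree whose pairwise spanning-subtree lengths mirror the
#: rodent/primate scale used for conservation filtering (mouse-rat 0.161,
#: mouse-human 0.453, mouse-rat-human 0.537 substitutions/site)
DEFAULT_TREE = ("(((mouse:0.077,rat:0.084):0.1,human:0.276):0.05,dog:0.25);")


@dataclass
class PlantSpec:
    """One motif to plant: a PWM, a mean per-promoter site count, and a
    positional law for the site center ("uniform" or ("gaussian", mu, sd)
    in TSS-relative bp)."""

    pwm: Pwm
    mean_sites: float
    law: object = "uniform"


@dataclass
class SimConfig:
    """Study conditions for the synthetic promoter generator."""

    n_promoters: int = 314
    L: int = 200
    gc_target: float = 0.364
    planted: list[PlantSpec] = field(default_factory=list)
    cons_beta: tuple[float, float] = (2.0, 5.0)
    cons_boost: float = 0.4
    tree: str = DEFAULT_TREE
    loss_rate: float = 2.0
    turnover_slide: float = 8.0
    duplicate_pairs: int = 0
    duplicate_sub_rate: float = 0.05
    seed: int = 0
    markov_persistence: float = 0.1  # first-order autocorrelation of the chain

    def __post_init__(self):
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        for spec in self.planted:
            if spec.mean_sites < 0:
                raise ValueError("mean site count must be >= 0")
            if spec.pwm.length > self.L:
                raise ValueError(
                    f"planted site {spec.pwm.id} ({spec.pwm.length} bp) exceeds "
                    f"promoter length {self.L}")


# ---------------------------------------------------------------------------
# demonstration PWMs


def _counts_from_consensus(consensus: str, strong: float = 0.85,
                           weak_pairs: dict | None = None) -> np.ndarray:
    """Counts matrix from a consensus string; lowercase n gives a flat
    column, uppercase letters a dominant base."""
    L = len(consensus)
    counts = np.full((4, L), 5.0)
    for i, c in enumerate(consensus):
        if c == "n":
            continue
        b = _BASES.index(c.upper())
        counts[:, i] = (1 - strong) * 100 / 3.0
        counts[b, i] = strong * 100
    return counts


def make_oe_pwm(opt_threshold: float = 0.85) -> Pwm:
    """A 21-bp O/E-like matrix (GC-rich core TCCC..GGGA on an AT background)."""
    consensus = "nnTTCCCnnGGGAGnnnnnnn"
    return Pwm.from_counts("V$SYN_OE_01", _counts_from_consensus(consensus),
                           family_id="V$SYN_OE", opt_threshold=opt_threshold)


def make_tata_pwm(opt_threshold: float = 0.85) -> Pwm:
    """An 11-bp TATA-box-like matrix (degenerate, AT-rich)."""
    consensus = "nTATAAAnnnn"
    return Pwm.from_counts("O$SYN_TBP_01", _counts_from_consensus(consensus, 0.8),
                           family_id="O$SYN_TBP", opt_threshold=opt_threshold)


def make_decoy_pwms(n: int, length: int = 10, seed: int = 0,
                    opt_threshold: float = 0.85) -> list[Pwm]:
    """Random sharp decoy matrices, one per synthetic family."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        counts = np.full((4, length), 5.0)
        for j in range(length):
            b = int(rng.integers(4))
            counts[:, j] = 5.0
            counts[b, j] = 85.0
        out.append(Pwm.from_counts(f"V$DECOY{i:03d}_01", counts,
                                   family_id=f"V$DECOY{i:03d}",
                                   opt_threshold=opt_threshold))
    return out


# ---------------------------------------------------------------------------
# promoter simulation


def _transition_matrix(gc: float, rho: float) -> np.ndarray:
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    P = (1 - rho) * np.tile(pi, (4, 1)) + rho * np.eye(4)
    return P


def _markov_sequence(n: int, P: np.ndarray, pi: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    out[0] = np.searchsorted(np.cumsum(pi), u[0], side="right")
    for i in range(1, n):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i], side="right")
    return np.clip(out, 0, 3)


def simulate_promoters(cfg: SimConfig):
    """Generate a synthetic promoter set and the truth list of planted sites.

    Background is a first-order Markov chain whose stationary GC equals
    ``cfg.gc_target``; per promoter, each planted motif contributes
    ``Poisson(mean_sites)`` instances at centers drawn from its
    positional law, sampled column-wise from the PWM and spliced in on
    a random strand, avoiding overlap between planted sites.  Both the
    L-bp promoter and the preceding L-bp control region are generated.
    Returns ``(PromoterSet, truth)`` with truth entries as
    :class:`~promoscan.pwm.SiteHit` in TSS-relative coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.L
    pi = np.array([(1 - cfg.gc_target) / 2, cfg.gc_target / 2,
                   cfg.gc_target / 2, (1 - cfg.gc_target) / 2])
    P = _transition_matrix(cfg.gc_target, cfg.markov_persistence)

    promoters, truth = [], []
    for i in range(cfg.n_promoters):
        pid = f"synp{i:04d}"
        codes = _markov_sequence(2 * L, P, pi, rng)
        occupied: list[tuple[int, int]] = []
        for spec in cfg.planted:
            m = spec.pwm.length
            k = rng.poisson(spec.mean_sites)
            for _ in range(k):
                start = None
                for _ in range(20):  # rejection sampling against overlaps
                    cand = _draw_start(spec.law, L, m, rng)
                    if cand is None:
                        continue
                    idx0 = 2 * L + cand
                    if all(idx0 + m <= s or idx0 >= e for s, e in occupied):
                        start = cand
                        break
                if start is None:
                    continue
                site = _sample_site(spec.pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    site = 3 - site[::-1]
                idx = 2 * L + start  # start is TSS-relative (negative)
                codes[idx:idx + m] = site
                occupied.append((idx, idx + m))
                truth.append(SiteHit(promoter_id=pid, start=start, end=start + m,
                                     strand=strand, pwm_id=spec.pwm.id,
                                     family_id=spec.pwm.family_id, score=1.0))
        seq = "".join(_BASES[c] for c in codes)
        promoters.append(Promoter(id=pid, sequence=seq[L:], preceding=seq[:L],
                                  chrom="chrSYN", tss=(i + 1) * 10 * L, strand="+"))
    truth.sort(key=lambda h: (h.promoter_id, h.start))
    return PromoterSet(promoters), truth


def _draw_start(law, L: int, m: int, rng) -> int | None:
    """TSS-relative start of a site whose center follows the positional law."""
    if law == "uniform":
        return int(rng.integers(-L, -m + 1))
    kind = law[0]
    if kind != "gaussian":
        raise ValueError(f"unknown positional law {law!r}")
    _, mu, sd = law
    for _ in range(100):
        center = rng.normal(mu, sd)
        start = int(round(center - m / 2.0))
        if -L <= start and start + m <= 0:
            return start
    return None


def _sample_site(pwm: Pwm, rng) -> np.ndarray:
    cum = np.cumsum(pwm.frequencies, axis=0)
    u = rng.random(pwm.length)
    return np.array([int(np.searchsorted(cum[:, j], u[j], side="right"))
                     for j in range(pwm.length)], dtype=np.int8).clip(0, 3)


# ---------------------------------------------------------------------------
# conservation simulation


def simulate_conservation(truth, promoter_ids, L: int = 200,
                          base_law: tuple[float, float] = (2.0, 5.0),
                          boost: float = 0.4, seed: int = 0):
    """Per-promoter conservation tracks: iid Beta background, boosted in
    planted sites (clipped to [0, 1]).

    Returns a dict promoter_id -> length-L score vector in the promoter
    frame (index 0 at TSS-relative -L).
    """
    if boost < 0:
        raise ValueError("boost must be >= 0")
    rng = np.random.default_rng(seed)
    a, b = base_law
    tracks = {pid: rng.beta(a, b, size=L) for pid in promoter_ids}
    for h in truth:
        if h.promoter_id not in tracks:
            continue
        lo, hi = h.start + L, h.end + L
        vec = tracks[h.promoter_id]
        vec[max(lo, 0):min(hi, L)] = np.minimum(
            1.0, vec[max(lo, 0):min(hi, L)] + boost)
    return tracks


# ---------------------------------------------------------------------------
# cross-species turnover simulation


def simulate_species_sets(truth, promoters: PromoterSet, tree=DEFAULT_TREE,
                          loss_rate: float = 2.0, slide_jitter: float = 8.0,
                          reference: str = "mouse", seed: int = 0):
    """Per-species site sets with turnover, plus trivial alignments.

    Each planted site survives on a non-reference leaf with probability
    ``exp(-loss_rate * d)`` where ``d`` is the patristic distance from
    the reference; survivors are displaced by ``round(N(0,
    slide_jitter))`` bp (clipped to the promoter).  Alignments are
    gapless (every species carries the reference sequence), so
    alignment column equals ungapped position; site coordinates are in
    the promoter index frame [0, L).

    Returns ``(species_sites, alignments)`` where species_sites maps
    species -> promoter_id -> list of (start, end), reference included.
    """
    import dendropy

    if loss_rate < 0 or slide_jitter < 0:
        raise ValueError("rates must be >= 0")
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=str(tree), schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in t.taxon_namespace}
    if reference not in taxa:
        raise KeyError(f"reference species {reference!r} not in tree")
    dist = {sp: (0.0 if sp == reference
                 else pdm.patristic_distance(taxa[reference], taxa[sp]))
            for sp in taxa}

    rng = np.random.default_rng(seed)
    L = promoters.L
    species = sorted(taxa)
    sites: dict[str, dict[str, list[tuple[int, int]]]] = {
        sp: {pid: [] for pid in promoters.ids} for sp in species}
    for h in truth:
        start, end = h.start + L, h.end + L  # promoter index frame
        for sp in species:
            if sp == reference:
                sites[sp][h.promoter_id].append((start, end))
                continue
            if rng.random() >= math.exp(-loss_rate * dist[sp]):
                continue
            shift = int(round(rng.normal(0.0, slide_jitter)))
            s = min(max(start + shift, 0), L - (end - start))
            sites[sp][h.promoter_id].append((s, s + (end - start)))

    alignments = [PromoterAlignment(promoter_id=p.id,
                                    rows={sp: p.sequence for sp in species},
                                    reference=reference)
                  for p in promoters]
    return sites, alignments


# ---------------------------------------------------------------------------
# duplicates


def simulate_duplicates(promoters: PromoterSet, n_pairs: int,
                        sub_rate: float = 0.05, seed: int = 0):
    """Augment a promoter set with mutated copies of its first *n_pairs*
    members; returns ``(augmented_set, truth_pairs)``.

    Each base of a copy mutates to a different base with probability
    *sub_rate* (0 <= sub_rate <= 0.3)."""
    if not 0 <= sub_rate <= 0.3:
        raise ValueError("sub_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    out = list(promoters.promoters)
    pairs = []
    for p in promoters.promoters[:n_pairs]:
        dup_id = f"{p.id}_dup"
        out.append(Promoter(id=dup_id, sequence=_mutate(p.sequence, sub_rate, rng),
                            preceding=(None if p.preceding is None
                                       else _mutate(p.preceding, sub_rate, rng)),
                            chrom=p.chrom, strand=p.strand))
        pairs.append((p.id, dup_id))
    return PromoterSet(out, offset=promoters.offset), pairs


def _mutate(seq: str, rate: float, rng) -> str:
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        old = chars[i].upper()
        if old not in _BASES:
            continue
        choices = [b for b in _BASES if b != old]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)
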