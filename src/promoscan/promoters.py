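"""TSS-anchored promoter dataset construction.

Builds a non-redundant promoter set from gene annotations and
cDNA/RACE-to-genome alignments: per-gene genomic domains, TSS inference
with exon merging and structural filters, removal of recent duplicates
(synonymous divergence or flank identity, single-linkage clustering),
strand-aware promoter extraction, and positional profiles (site
coverage, GC content).

Coordinate conventions: genomic intervals are 0-based half-open.  The
recorded TSS of a gene is the *upstream boundary* of its transcript:
for a + strand gene the promoter occupies genomic ``[tss - L, tss)``;
for a - strand gene it occupies ``[tss, tss + L)`` and is
reverse-complemented so that every promoter sequence reads 5'->3'
toward the TSS.  In the TSS-relative frame the promoter covers
``[-L, 0)`` with position -1 adjacent to the TSS.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneDomain:
    """Genomic domain of a gene: the region whose cDNAs it may claim."""

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    domain_start: int
    domain_end: int
    pseudogene: bool = False


@dataclass
class Promoter:
    """One TSS-anchored promoter region."""

    id: str
    sequence: str
    chrom: str | None = None
    tss: int | None = None
    strand: str = "+"
    preceding: str | None = None
    scores: np.ndarray | None = None


class PromoterSet:
    """A collection of equal-length promoters sharing the TSS-relative frame.

    ``offset`` is the TSS-relative coordinate of sequence position 0
    (``-L`` for promoter regions, ``-2L`` for the preceding control
    regions).
    """

    def __init__(self, promoters: list[Promoter], offset: int | None = None):
        self.promoters = list(promoters)
        if self.promoters:
            L = len(self.promoters[0].sequence)
            for p in self.promoters:
                if len(p.sequence) != L:
                    raise ValueError(
                        f"promoter {p.id} has length {len(p.sequence)}, expected {L}")
        else:
            L = 0
        self.L = L
        self.offset = -L if offset is None else offset

    def __len__(self):
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.promoters]

    def sequences(self) -> dict[str, str]:
        return {p.id: p.sequence for p in self.promoters}

    def get(self, pid: str) -> Promoter:
        for p in self.promoters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def subset(self, ids) -> "PromoterSet":
        wanted = set(ids)
        return PromoterSet([p for p in self.promoters if p.id in wanted],
                           offset=self.offset)

    def preceding_set(self) -> "PromoterSet":
        """The preceding control regions, framed at offset -2L."""
        regs = []
        for p in self.promoters:
            if p.preceding is None:
                raise ValueError(f"promoter {p.id} has no preceding region")
            regs.append(Promoter(id=p.id, sequence=p.preceding, chrom=p.chrom,
                                 tss=p.tss, strand=p.strand))
        return PromoterSet(regs, offset=self.offset - self.L)

    def score_tracks(self) -> dict[str, np.ndarray]:
        return {p.id: p.scores for p in self.promoters if p.scores is not None}

    def to_fasta(self, path) -> None:
        """Write promoter FASTA; headers carry genome coordinates and strand."""
        with open(path, "w") as fh:
            for p in self.promoters:
                coord = ""
                if p.chrom is not None and p.tss is not None:
                    if p.strand == "+":
                        gstart, gend = p.tss - self.L, p.tss
                    else:
                        gstart, gend = p.tss, p.tss + self.L
                    coord = f" {p.chrom}:{gstart}-{gend}({p.strand})"
                fh.write(f">{p.id}{coord}\n{p.sequence}\n")

    def attach_preceding(self, path) -> None:
        """Attach preceding control regions from a FASTA keyed by promoter id."""
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        for p in self.promoters:
            if p.id not in seqs:
                raise KeyError(f"no preceding region for promoter {p.id}")
            p.preceding = seqs[p.id]

    @classmethod
    def from_fasta(cls, path, offset: int | None = None) -> "PromoterSet":
        from Bio import SeqIO

        proms = []
        for rec in SeqIO.parse(str(path), "fasta"):
            chrom = tss = None
            strand = "+"
            parts = rec.description.split()
            if len(parts) > 1 and ":" in parts[1]:
                loc = parts[1]
                chrom, rest = loc.split(":", 1)
                span, strand = rest[:-3], rest[-2]
                gstart, gend = (int(x) for x in span.split("-"))
                tss = gend if strand == "+" else gstart
            proms.append(Promoter(id=rec.id, sequence=str(rec.seq), chrom=chrom,
                                  tss=tss, strand=strand))
        return cls(proms, offset=offset)


# ---------------------------------------------------------------------------
# gene domains and TSS inference


def assign_gene_domains(or_orfs, max_upstream: int = 100_000,
                        edge_margin: int = 1_000) -> list[GeneDomain]:
    """Assign each gene a genomic domain for claiming cDNA alignments.

    *or_orfs* is an iterable of records ``(gene_id, chrom, start, end,
    strand[, pseudogene])`` (or a DataFrame with those columns).  The
    upstream edge sits ``edge_margin`` bp closer than the nearest edge
    of the neighboring ORF upstream (or ``max_upstream`` bp from the ORF
    start when no neighbor is that close); the downstream edge is
    ``edge_margin`` bp past the ORF end.  Both are taken on the gene's
    strand.  Neighbors closer than ``edge_margin`` clip the upstream
    extent to zero with a warning.
    """
    records = _orf_records(or_orfs)
    by_chrom: dict[str, list] = {}
    for rec in records:
        by_chrom.setdefault(rec[1], []).append(rec)

    domains = []
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r[2], r[3]))
        for i, (gid, _, s, e, strand, pseudo) in enumerate(recs):
            if strand == "+":
                prev_edge = max((r[3] for r in recs[:i] if r[3] <= s), default=None)
                if prev_edge is not None and s - prev_edge <= max_upstream:
                    dstart = prev_edge + edge_margin
                    if dstart > s:
                        warnings.warn(f"{gid}: neighboring ORF within {edge_margin} bp; "
                                      "upstream extent clipped to 0")
                        dstart = s
                else:
                    dstart = max(s - max_upstream, 0)
                dend = e + edge_margin
            else:
                nxt_edge = min((r[2] for r in recs[i + 1:] if r[2] >= e), default=None)
                if nxt_edge is not None and nxt_edge - e <= max_upstream:
                    dend = nxt_edge - edge_margin
                    if dend < e:
                        warnings.warn(f"{gid}: neighboring ORF within {edge_margin} bp; "
                                      "upstream extent clipped to 0")
                        dend = e
                else:
                    dend = e + max_upstream
                dstart = max(s - edge_margin, 0)
            domains.append(GeneDomain(gene_id=gid, chrom=chrom, strand=strand,
                                      orf_start=s, orf_end=e,
                                      domain_start=dstart, domain_end=dend,
                                      pseudogene=pseudo))
    domains.sort(key=lambda d: (d.chrom, d.domain_start))
    return domains


def _orf_records(or_orfs):
    try:
        import pandas as pd
        if isinstance(or_orfs, pd.DataFrame):
            or_orfs = or_orfs.itertuples(index=False)
    except ImportError:  # pragma: no cover
        pass
    out = []
    for rec in or_orfs:
        rec = tuple(rec)
        gid, chrom, s, e, strand = rec[:5]
        pseudo = bool(rec[5]) if len(rec) > 5 else False
        out.append((gid, chrom, int(s), int(e), strand, pseudo))
    return out


def infer_tss(cdna_alignments, domains: list[GeneDomain],
              merge_gap: int = 10) -> "pd.DataFrame":
    """Infer one TSS per gene from cDNA/RACE alignment blocks.

    *cdna_alignments* is an iterable of ``(cdna_id, chrom, strand,
    blocks)`` where ``blocks`` is a list of ``(start, end)`` genomic
    intervals.  cDNAs overlapping more than one gene domain are
    discarded; cDNAs on the wrong strand of their domain are discarded
    with a log entry.  Per gene, the union of cDNA blocks and the ORF
    forms the transcribed segments; gaps smaller than *merge_gap* are
    merged.  Genes are then discarded when they have a single merged
    exon, are flagged as pseudogenes, or have an intron entirely
    downstream of the ORF.  The TSS is the most upstream transcribed
    base, recorded as the upstream transcript boundary.

    Returns a DataFrame (gene_id, chrom, tss, strand) plus a ``.attrs``
    dict of discard tallies.
    """
    import pandas as pd

    tally = {"multi_domain_cdna": 0, "wrong_strand_cdna": 0, "unassigned_cdna": 0,
             "single_exon_gene": 0, "pseudogene": 0, "intron_downstream_of_orf": 0}
    dom_by_gene = {d.gene_id: d for d in domains}
    gene_blocks: dict[str, list[tuple[int, int]]] = {g: [] for g in dom_by_gene}

    for cdna_id, chrom, strand, blocks in cdna_alignments:
        blocks = [(int(s), int(e)) for s, e in blocks]
        lo, hi = min(s for s, _ in blocks), max(e for _, e in blocks)
        touching = [d for d in domains
                    if d.chrom == chrom and lo < d.domain_end and hi > d.domain_start]
        if len(touching) > 1:
            tally["multi_domain_cdna"] += 1
            continue
        if not touching:
            tally["unassigned_cdna"] += 1
            continue
        dom = touching[0]
        if strand != dom.strand:
            logger.info("cDNA %s on wrong strand of domain %s; discarded",
                        cdna_id, dom.gene_id)
            tally["wrong_strand_cdna"] += 1
            continue
        gene_blocks[dom.gene_id].extend(blocks)

    rows = []
    for gid, dom in dom_by_gene.items():
        blocks = gene_blocks[gid]
        if not blocks:
            continue
        segments = merge_intervals(blocks + [(dom.orf_start, dom.orf_end)],
                                   gap=merge_gap)
        if len(segments) == 1:
            tally["single_exon_gene"] += 1
            continue
        if dom.pseudogene:
            tally["pseudogene"] += 1
            continue
        if _has_downstream_intron(segments, dom):
            tally["intron_downstream_of_orf"] += 1
            continue
        tss = segments[0][0] if dom.strand == "+" else segments[-1][1]
        rows.append((gid, dom.chrom, tss, dom.strand))

    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    df.attrs["discarded"] = tally
    logger.info("TSS inference: %d genes kept; discards: %s", len(df), tally)
    return df


def merge_intervals(intervals, gap: int = 0) -> list[tuple[int, int]]:
    """Union of half-open intervals, merging gaps smaller than *gap*."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (gap > 0 and s - out[-1][1] < gap)):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _has_downstream_intron(segments, dom: GeneDomain) -> bool:
    if dom.strand == "+":
        return any(s >= dom.orf_end for s, _ in segments[1:])
    return any(e <= dom.orf_start for _, e in segments[:-1])


# ---------------------------------------------------------------------------
# recent-duplicate detection


_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_NT = "ACGT"


def _codon_syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (NG86 site counting)."""
    aa = _GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if _GENETIC_CODE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over substitution pathways; pathways through stop codons are excluded
    when possible."""
    from itertools import permutations

    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results, results_with_stops = [], []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _GENETIC_CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            if _GENETIC_CODE[cur] == _GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results_with_stops if through_stop else results).append((sd, nd))
    pool = results or results_with_stops
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    return sd, nd


def ng86_ds(seq1: str, seq2: str) -> float | None:
    """Synonymous divergence dS by the Nei–Gojobori (1986) method with
    Jukes–Cantor correction.  Returns ``None`` when the correction is
    undefined (saturation).

    Codons containing non-ACGT characters or stop codons are skipped.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    n = min(len(seq1), len(seq2)) // 3 * 3
    S = Sd = 0.0
    for i in range(0, n, 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if any(b not in _NT for b in c1 + c2):
            continue
        if _GENETIC_CODE[c1] == "*" or _GENETIC_CODE[c2] == "*":
            continue
        S += (_codon_syn_sites(c1) + _codon_syn_sites(c2)) / 2.0
        sd, _ = _pathway_counts(c1, c2)
        Sd += sd
    if S == 0:
        return None
    ps = Sd / S
    arg = 1.0 - 4.0 * ps / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def local_flank_alignment(seq1: str, seq2: str, word: int = 12,
                          xdrop: int = 20, match: int = 1, mismatch: int = -1):
    """Best ungapped local alignment seeded on shared *word*-mers.

    Returns ``(span, identity)`` of the longest X-drop extension over
    all seed diagonals, or ``(0, 0.0)`` when no seed is shared.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq1) - word + 1):
        index.setdefault(seq1[i:i + word], []).append(i)

    best = (0, 0.0)
    seen_diags: set[int] = set()
    for j in range(len(seq2) - word + 1):
        for i in index.get(seq2[j:j + word], ()):
            diag = i - j
            if diag in seen_diags:
                continue
            seen_diags.add(diag)
            span, ident = _xdrop_extend(seq1, seq2, i, j, word, xdrop, match, mismatch)
            if span > best[0] or (span == best[0] and ident > best[1]):
                best = (span, ident)
    return best


def _xdrop_extend(s1, s2, i, j, word, xdrop, match, mismatch):
    """Extend a word-length seed at (i, j) in both directions with X-drop."""

    def extend(p1, p2, step):
        # p1/p2: first positions to examine; step is +1 or -1
        score = best_score = 0
        off = best_off = 0
        while 0 <= p1 < len(s1) and 0 <= p2 < len(s2):
            score += match if s1[p1] == s2[p2] else mismatch
            off += 1
            if score > best_score:
                best_score, best_off = score, off
            if best_score - score > xdrop:
                break
            p1 += step
            p2 += step
        return best_off

    right = extend(i + word, j + word, +1)
    left = extend(i - 1, j - 1, -1)
    start1, start2 = i - left, j - left
    span = word + left + right
    matches = sum(1 for k in range(span) if s1[start1 + k] == s2[start2 + k])
    return span, matches / span if span else 0.0


def pairwise_similarity(orf_seqs: dict, flank_seqs: dict,
                        ds_threshold: float = 0.3,
                        min_span: int = 200, min_identity: float = 0.70):
    """Flag recently duplicated gene pairs.

    A pair is "similar" when its coding regions show NG86 synonymous
    divergence below *ds_threshold*, or when a seeded ungapped local
    alignment of the 2-kb flanks spans at least *min_span* bp at
    *min_identity* or better.  Returns a list of ``(id1, id2,
    criterion)`` with criterion "dS", "identity" or "dS+identity";
    saturated dS comparisons contribute no dS flag.
    """
    ids = sorted(set(orf_seqs) | set(flank_seqs))
    pairs = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            crit = []
            if a in orf_seqs and b in orf_seqs:
                ds = ng86_ds(orf_seqs[a], orf_seqs[b])
                if ds is not None and ds < ds_threshold:
                    crit.append("dS")
            if a in flank_seqs and b in flank_seqs:
                span, ident = local_flank_alignment(flank_seqs[a], flank_seqs[b])
                if span >= min_span and ident >= min_identity:
                    crit.append("identity")
            if crit:
                pairs.append((a, b, "+".join(crit)))
    return pairs


def dedup_single_linkage(items, pairs, seed: int = 42):
    """Single-linkage clusters from similarity pairs, one representative each.

    Clusters are the connected components of the pair graph; the
    representative of each cluster is chosen by a seeded RNG
    (deterministic given *seed*); singletons represent themselves.
    Returns ``(clusters, representatives)`` with clusters sorted by
    their smallest member.
    """
    items = list(items)
    index = {it: i for i, it in enumerate(items)}
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in pairs:
        a, b = pair[0], pair[1]
        if a not in index or b not in index:
            raise KeyError(f"pair ({a}, {b}) references unknown item")
        ra, rb = find(index[a]), find(index[b])
        if ra != rb:
            parent[ra] = rb

    comp: dict[int, list] = {}
    for it, i in index.items():
        comp.setdefault(find(i), []).append(it)
    clusters = sorted((sorted(c) for c in comp.values()), key=lambda c: c[0])

    rng = np.random.default_rng(seed)
    reps = [c[int(rng.integers(len(c)))] for c in clusters]
    return clusters, reps


# ---------------------------------------------------------------------------
# promoter extraction and profiles


def extract_promoters(genome, tss_table, L: int = 200) -> PromoterSet:
    """Extract L-bp promoter and preceding regions around each TSS.

    *genome* is a FASTA path (read through pyfaidx) or a mapping of
    chromosome name to sequence.  *tss_table* is an iterable of
    ``(gene_id, chrom, tss, strand)`` or a DataFrame with those columns.
    Promoters falling outside their contig are dropped with a warning.
    """
    close = None
    if not hasattr(genome, "keys"):
        from pyfaidx import Fasta

        genome = Fasta(str(genome), as_raw=True)
        close = genome.close

    try:
        import pandas as pd
        if isinstance(tss_table, pd.DataFrame):
            tss_table = list(tss_table[["gene_id", "chrom", "tss", "strand"]]
                             .itertuples(index=False))
    except ImportError:  # pragma: no cover
        pass

    proms = []
    try:
        for gid, chrom, tss, strand in tss_table:
            tss = int(tss)
            contig = genome[chrom]
            clen = len(contig)
            if strand == "+":
                gstart, gend = tss - 2 * L, tss
            else:
                gstart, gend = tss, tss + 2 * L
            if gstart < 0 or gend > clen:
                warnings.warn(f"{gid}: promoter window outside contig {chrom}; dropped")
                continue
            block = str(contig[gstart:gend])
            if strand == "+":
                preceding, seq = block[:L], block[L:]
            else:
                block = reverse_complement(block)
                preceding, seq = block[:L], block[L:]
            proms.append(Promoter(id=gid, sequence=seq, chrom=chrom, tss=tss,
                                  strand=strand, preceding=preceding))
    finally:
        if close is not None:
            close()
    return PromoterSet(proms)


def positional_profile(tracks, window: int = 20, slide: int = 1,
                       offset: int | None = None):
    """Cross-promoter average of per-base tracks, smoothed in sliding windows.

    *tracks* is a 2-D array or list of equal-length vectors in the
    shared TSS-relative frame (binary site indicators, GC indicators or
    scalar scores; NaN allowed for missing).  Values are averaged across
    promoters per position, then mean-smoothed in windows of *window*
    bp advanced by *slide* bp.  Returns ``(positions, values)`` with
    positions at window centers, in the TSS-relative frame when
    *offset* is given (default ``-length``).
    """
    mat = np.asarray(list(tracks), dtype=float)
    if mat.ndim == 1:
        mat = mat[None, :]
    length = mat.shape[1]
    if window > length:
        raise ValueError(f"window {window} exceeds track length {length}")
    if offset is None:
        offset = -length
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col = np.nanmean(mat, axis=0)
    starts = np.arange(0, length - window + 1, slide)
    vals = np.array([np.nanmean(col[s:s + window]) for s in starts])
    centers = starts + (window - 1) / 2.0 + offset
    return centers, vals


def coverage_tracks(promoter_set: PromoterSet, hits) -> np.ndarray:
    """Binary per-base matrix: promoter has >=1 hit covering the base."""
    L = promoter_set.L
    off = promoter_set.offset
    idx = {pid: i for i, pid in enumerate(promoter_set.ids)}
    mat = np.zeros((len(promoter_set), L))
    for h in hits:
        if h.promoter_id not in idx:
            continue
        lo = max(h.start - off, 0)
        hi = min(h.end - off, L)
        if hi > lo:
            mat[idx[h.promoter_id], lo:hi] = 1.0
    return mat


def gc_tracks(promoter_set: PromoterSet) -> np.ndarray:
    """Binary per-base G/C indicator matrix (NaN at masked bases)."""
    mat = np.full((len(promoter_set), promoter_set.L), np.nan)
    for i, p in enumerate(promoter_set):
        arr = np.frombuffer(p.sequence.upper().encode(), dtype=np.uint8)
        gc = (arr == ord("G")) | (arr == ord("C"))
        known = gc | (arr == ord("A")) | (arr == ord("T"))
        row = np.where(known, gc.astype(float), np.nan)
        mat[i] = row
    return mat
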