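"""Turnover-aware cross-species conservation of predicted sites.

A site predicted in the reference species is scored by the set of
other species whose own predicted sites, mapped through a multiple
alignment of the promoter, land within a configurable "slide" distance
of it (binding-site turnover: a functional site may move during
evolution).  The evidence for a site is the total branch length of the
minimal subtree connecting its supporting species; sites below a
tree-length threshold are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PromoterAlignment:
    """A per-promoter multiple alignment over a shared column frame.

    ``rows`` maps species to gapped strings of equal length; the
    reference row, ungapped, equals the promoter sequence.
    """

    promoter_id: str
    rows: dict[str, str]
    reference: str

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"alignment {self.promoter_id}: rows have unequal lengths {lengths}")
        if self.reference not in self.rows:
            raise ValueError(f"alignment {self.promoter_id}: no reference row "
                             f"{self.reference!r}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


def read_promoter_alignments(path, reference: str | None = None):
    """Read per-promoter alignment blocks from a MAF file.

    Each MAF block becomes one :class:`PromoterAlignment`; sequence
    sources are expected as ``species.promoter_id``.  The reference is
    the first row of each block unless given.
    """
    from Bio import AlignIO

    out = []
    for block in AlignIO.parse(str(path), "maf"):
        rows, pid, ref = {}, None, reference
        for rec in block:
            species, _, rest = rec.id.partition(".")
            rows[species] = str(rec.seq)
            if pid is None:
                pid = rest or rec.id
            if ref is None:
                ref = species
        out.append(PromoterAlignment(promoter_id=pid, rows=rows, reference=ref))
    return out


def alignment_coordinate_maps(aln: PromoterAlignment) -> dict[str, dict]:
    """Bijections between each species' ungapped positions and columns.

    Returns per species ``{"col_of_pos": array, "pos_of_col": array}``;
    ``pos_of_col`` is -1 at columns where the species has a gap (exact
    lookups only).
    """
    maps = {}
    for species, row in aln.rows.items():
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        not_gap = arr != ord("-")
        col_of_pos = np.flatnonzero(not_gap)
        pos_of_col = np.full(arr.size, -1, dtype=np.intp)
        pos_of_col[col_of_pos] = np.arange(col_of_pos.size)
        maps[species] = {"col_of_pos": col_of_pos, "pos_of_col": pos_of_col}
    return maps


def _to_columns(site, cmap) -> tuple[int, int] | None:
    """Map an ungapped half-open interval to an alignment column interval."""
    start, end = site
    col_of_pos = cmap["col_of_pos"]
    if start < 0 or end > col_of_pos.size or end <= start:
        return None
    return int(col_of_pos[start]), int(col_of_pos[end - 1]) + 1


def cross_species_presence(ref_sites, other_species_sites, maps,
                           slide_w: int = 50, reference: str = "ref"):
    """Supporting species set for each reference site.

    *ref_sites* are ``(start, end)`` intervals in the reference
    species' ungapped coordinates; *other_species_sites* maps species
    to their own ungapped site intervals.  A species supports a
    reference site when one of its sites, mapped to alignment columns,
    lies within *slide_w* columns of the reference site's columns
    (``slide_w = 0`` requires actual overlap).  The reference species
    is always included in the support set.
    """
    ref_map = maps[reference]
    supports = []
    for site in ref_sites:
        cols = _to_columns(site, ref_map)
        support = {reference}
        if cols is not None:
            rs, re = cols
            for species, sites in other_species_sites.items():
                if species not in maps or species == reference:
                    continue
                cmap = maps[species]
                for other in sites:
                    oc = _to_columns(other, cmap)
                    if oc is None:
                        continue
                    os_, oe = oc
                    sep = max(os_ - re, rs - oe)  # negative iff overlapping
                    if (sep < 0) if slide_w == 0 else (sep <= slide_w):
                        support.add(species)
                        break
        supports.append(support)
    return supports


# ---------------------------------------------------------------------------
# species tree


def _as_tree(tree):
    import dendropy

    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path
        return dendropy.Tree.get(path=text, schema="newick")
    return dendropy.Tree.get(data=text, schema="newick")


def subtree_branch_length(tree, species_subset) -> float:
    """Total branch length of the minimal subtree connecting *species_subset*.

    Branches above the subset's MRCA are excluded; a singleton subset
    has length 0.  Unknown species raise ``KeyError`` naming them.
    """
    t = _as_tree(tree)
    subset = set(species_subset)
    if not subset:
        raise ValueError("species subset must be non-empty")
    names = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    for sp in subset:
        if sp not in names:
            raise KeyError(f"species {sp!r} not found in tree")
    if len(subset) == 1:
        return 0.0
    # an edge belongs to the spanning subtree iff the clade below it
    # contains some but not all of the subset
    total = 0.0
    k = len(subset)
    counts = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in subset else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        if 1 <= c <= k - 1 and node.edge.length:
            total += node.edge.length
    return total


def tree_length(tree) -> float:
    t = _as_tree(tree)
    return sum(e.length or 0.0 for e in t.preorder_edge_iter())


def filter_conserved_sites(sites_with_support, tree, min_tree_len: float = 0.17,
                           promoter_ids=None):
    """Keep sites whose supporting-species subtree length reaches the cutoff.

    *sites_with_support* is a list of ``(site, support_set)`` where
    ``site`` carries a ``promoter_id`` attribute (e.g. a SiteHit) or is
    a ``(promoter_id, start, end)`` tuple.  Returns ``(kept_sites,
    per_promoter_counts, fraction_with_site)``; the fraction is taken
    over *promoter_ids* when given (promoters without sites count in
    the denominator), else over the promoters present in the input.
    """
    t = _as_tree(tree)
    kept = []
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for site, support in sites_with_support:
        pid = getattr(site, "promoter_id", None) or site[0]
        seen.add(pid)
        if subtree_branch_length(t, support) >= min_tree_len:
            kept.append(site)
            counts[pid] = counts.get(pid, 0) + 1
    universe = list(promoter_ids) if promoter_ids is not None else sorted(seen)
    for pid in universe:
        counts.setdefault(pid, 0)
    n = len(universe)
    frac = sum(1 for pid in universe if counts[pid] > 0) / n if n else float("nan")
    return kept, counts, frac


# ---------------------------------------------------------------------------
# orthologous promoter regions


def ortholog_region_merge(regions):
    """Collapse overlapping lifted-over promoter regions, keeping the most
    upstream window of each merged run.

    *regions* is an iterable of ``(chrom, start, end, strand)`` (or a
    BED6 path; name/score columns are ignored).  Same-strand,
    same-chromosome overlapping regions are merged; each merged run is
    replaced by its most upstream window of the input width ("upstream"
    is leftmost on +, rightmost on -).
    """
    if isinstance(regions, (str,)) or hasattr(regions, "read"):
        regions = _read_bed(regions)
    parsed = [(c, int(s), int(e), strand) for c, s, e, strand in regions]
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for c, s, e, strand in parsed:
        groups.setdefault((c, strand), []).append((s, e))

    out = []
    for (c, strand), ivs in sorted(groups.items()):
        ivs.sort()
        run: list[tuple[int, int]] = []
        run_hi = None
        for s, e in ivs:
            if run and s >= run_hi:
                out.append(_upstream_window(c, strand, run))
                run = []
            run.append((s, e))
            run_hi = e if run_hi is None or len(run) == 1 else max(run_hi, e)
        if run:
            out.append(_upstream_window(c, strand, run))
    out.sort()
    return out


def _upstream_window(chrom, strand, run):
    width = run[0][1] - run[0][0]
    lo = min(s for s, _ in run)
    hi = max(e for _, e in run)
    if strand == "+":
        return (chrom, lo, lo + width, strand)
    return (chrom, hi - width, hi, strand)


def _read_bed(path):
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) > 5 else "+"
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED at line {ln}: {line!r}") from exc
            out.append((chrom, start, end, strand))
    return out
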