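"""Pipeline orchestration: scan, three statistical tests, masking, re-run.

``run_pipeline`` executes the full analysis from one configuration:
PWM scans at both stringencies, per-family pruning, the binomial test
against the preceding regions, the dinucleotide-shuffle empirical
null, the conservation rank test, then masking of the dominant motif
(and TSS-proximal TATA boxes) from the real data *and* every control
dataset, and a complete second round on the masked data.  The output
is a per-family report table with three p-values and a three-character
significance code per family ('X' below the Bonferroni threshold, '+'
below the nominal alpha, '.' otherwise — the code legend is this
package's convention), plus the counts of families significant in
each intersection of the three tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from promoscan import conservation as cons
from promoscan import enrichment as enr
from promoscan import masking as msk
from promoscan.promoters import PromoterSet
from promoscan.pwm import Pwm, family_prune, hits_to_tsv, load_pwms, scan_sequences

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "family_id", "n_sites", "n_promoters_with_site",
    "n_control_region", "fold_vs_region", "p_binomial",
    "shuffle_mean", "fold_vs_shuffle", "p_shuffle", "p_shuffle_label",
    "p_cons_whole", "p_cons_core", "codes",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``m`` (the Bonferroni test count) defaults to the number of
    families actually tested.  ``mask_oe_family`` / ``mask_tata_family``
    name the families whose sites are masked before the second round;
    when both are None the post-mask round is skipped.
    """

    promoters_path: str | None = None
    preceding_path: str | None = None
    pwms_path: str | None = None
    pwm_format: str = "transfac"
    family_map_path: str | None = None
    scores_path: str | None = None
    expression_path: str | None = None
    L: int = 200
    threshold_modes: tuple[str, ...] = ("opt", "opt-0.1")
    B: int = enr.DEFAULT_B
    alpha: float = 0.05
    m: int | None = None
    mask_oe_family: str | None = None
    mask_tata_family: str | None = None
    tata_window: tuple[int, int] = msk.TATA_WINDOW
    strict_shuffle: bool = False
    seed: int = 0
    subset: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "threshold_modes" in data:
            data["threshold_modes"] = tuple(data["threshold_modes"])
        if "tata_window" in data:
            data["tata_window"] = tuple(data["tata_window"])
        return cls(**data)


def analyze_dataset(promoters: PromoterSet, pwms: list[Pwm], mode: str,
                    B: int, seed: int, tracks: dict | None = None,
                    mask: msk.MaskSet | None = None,
                    strict_shuffle: bool = False) -> pd.DataFrame:
    """All three statistical tests for one stringency on one dataset.

    When *mask* is given, the promoter, preceding and shuffled
    sequences and the score tracks are all masked at the same
    TSS-relative positions before counting (shuffles are taken of the
    unmasked sequence and re-masked, preserving composition).
    """
    mask_idx = mask.index_arrays(promoters.offset, promoters.L) if mask else None

    fam_ids, n_prom, with_site = enr.observed_family_counts(
        promoters, pwms, mode, mask_idx)
    preceding = promoters.preceding_set()
    _, n_prec, _ = enr.observed_family_counts(preceding, pwms, mode, mask_idx)
    shuffled = enr.shuffled_family_counts(promoters, pwms, B, seed, mode, mask_idx)

    if tracks is not None and mask is not None:
        tracks = msk.apply_mask_everywhere(mask, promoters,
                                           score_tracks=tracks)[3]
    hits = None
    if tracks is not None:
        scan_set = msk.mask_promoter_set(mask, promoters) if mask else promoters
        hits = family_prune(scan_sequences(scan_set, pwms, mode))
    pwm_by_id = {p.id: p for p in pwms}

    rows = []
    for i, fam in enumerate(fam_ids):
        k, m_ctrl = int(n_prom[i]), int(n_prec[i])
        if k == 0 and m_ctrl == 0:
            continue  # uninformative rows are not reported
        fold_r, p_binom = enr.binomial_enrichment(k, m_ctrl)
        fold_s, p_shuf = enr.shuffle_null_test(k, shuffled[:, i],
                                               strict=strict_shuffle)
        p_whole = p_core = float("nan")
        if tracks is not None:
            fam_hits = [h for h in hits if h.family_id == fam]
            if fam_hits:
                p_whole, _, _ = cons.wilcoxon_site_conservation(
                    tracks, fam_hits, promoters.L, "whole_site",
                    offset=promoters.offset)
                p_core, _, _ = cons.wilcoxon_site_conservation(
                    tracks, fam_hits, promoters.L, "core", pwms=pwm_by_id,
                    offset=promoters.offset)
        rows.append({
            "family_id": fam,
            "n_sites": k,
            "n_promoters_with_site": int(with_site[i]),
            "n_control_region": m_ctrl,
            "fold_vs_region": fold_r,
            "p_binomial": p_binom,
            "shuffle_mean": float(shuffled[:, i].mean()),
            "fold_vs_shuffle": fold_s,
            "p_shuffle": p_shuf,
            "p_shuffle_label": enr.format_empirical_p(p_shuf, B),
            "p_cons_whole": p_whole,
            "p_cons_core": p_core,
        })
    return pd.DataFrame(rows)


def _code(p: float, alpha: float, bonf: float) -> str:
    if not (isinstance(p, float) and math.isfinite(p)):
        return "."
    if p < bonf:
        return "X"
    if p < alpha:
        return "+"
    return "."


def summarize(rows: pd.DataFrame, alpha: float = 0.05,
              m: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Attach significance codes and compute the three-test intersections.

    The conservation test counts as passing when either the whole-site
    or the core variant passes.  Returns ``(table, venn)`` where venn
    maps subsets of {"binomial", "shuffle", "conservation"} (as sorted
    '+'-joined keys) to the number of families significant at the
    Bonferroni level in exactly that subset of tests.
    """
    df = rows.copy()
    if m is None:
        m = len(df) if len(df) else 1
    bonf = enr.bonferroni_threshold(alpha, m)
    cons_p = df[["p_cons_whole", "p_cons_core"]].min(axis=1, skipna=True)
    df["codes"] = [
        " ".join((_code(b, alpha, bonf), _code(s, alpha, bonf), _code(c, alpha, bonf)))
        for b, s, c in zip(df["p_binomial"], df["p_shuffle"], cons_p)
    ]
    sig = {
        "binomial": set(df.loc[df["p_binomial"] < bonf, "family_id"]),
        "shuffle": set(df.loc[df["p_shuffle"] < bonf, "family_id"]),
        "conservation": set(df.loc[cons_p < bonf, "family_id"]),
    }
    venn: dict[str, int] = {}
    tests = ["binomial", "shuffle", "conservation"]
    for mask_bits in range(1, 8):
        inc = [t for i, t in enumerate(tests) if mask_bits >> i & 1]
        exc = [t for t in tests if t not in inc]
        members = set.intersection(*(sig[t] for t in inc))
        for t in exc:
            members -= sig[t]
        venn["+".join(inc)] = len(members)
    df = df[[c for c in REPORT_COLUMNS if c in df.columns]]
    return df, venn


def run_pipeline(cfg: RunConfig, outdir=None, promoters: PromoterSet | None = None,
                 pwms: list[Pwm] | None = None, tracks: dict | None = None) -> dict:
    """Run the full analysis; returns a dict of report tables.

    Inputs may be given in memory or through the paths in *cfg*.
    Stage order: scan at each stringency -> family pruning ->
    enrichment (binomial + shuffle) -> conservation -> mask dominant
    motifs -> identical masking of all control data -> full re-run.
    Intermediates are written under *outdir* when given; the log
    records seeds and per-stage tallies.
    """
    if promoters is None:
        if cfg.promoters_path is None:
            raise ValueError("no promoters given (in memory or via promoters_path)")
        promoters = PromoterSet.from_fasta(cfg.promoters_path)
        if cfg.preceding_path is not None:
            promoters.attach_preceding(cfg.preceding_path)
    if pwms is None:
        if cfg.pwms_path is None:
            raise ValueError("no PWMs given (in memory or via pwms_path)")
        pwms, _ = load_pwms(cfg.pwms_path, cfg.pwm_format, cfg.family_map_path)
    if not pwms:
        raise ValueError("PWM library is empty")
    if cfg.subset:
        promoters = promoters.subset(cfg.subset)
    if tracks is None and cfg.scores_path is not None:
        tracks = cons.prepare_scores(cfg.scores_path, promoters)

    n_families = len({p.family_id for p in pwms})
    m = cfg.m if cfg.m is not None else n_families
    out: dict = {"config": asdict(cfg), "m": m, "n_promoters": len(promoters),
                 "n_families": n_families, "premask": {}, "premask_venn": {},
                 "postmask": {}, "postmask_venn": {}}

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "scan"
    try:
        all_hits = {}
        for mode in cfg.threshold_modes:
            all_hits[mode] = family_prune(scan_sequences(promoters, pwms, mode))
            if outdir is not None:
                hits_to_tsv(all_hits[mode], outdir / f"hits_premask_{_slug(mode)}.tsv")

        for mode in cfg.threshold_modes:
            stage = f"enrichment/conservation ({mode})"
            table = analyze_dataset(promoters, pwms, mode, cfg.B, cfg.seed,
                                    tracks=tracks, strict_shuffle=cfg.strict_shuffle)
            table, venn = summarize(table, cfg.alpha, m)
            out["premask"][mode] = table
            out["premask_venn"][mode] = venn
            if outdir is not None:
                table.to_csv(outdir / f"report_premask_{_slug(mode)}.tsv",
                             sep="\t", index=False)

        if cfg.mask_oe_family or cfg.mask_tata_family:
            stage = "masking"
            # the mask covers the full extent of every relaxed-stringency
            # site of the dominant family (unpruned: lower-scoring overlapping
            # sites must disappear too), plus TSS-proximal TATA sites at opt
            oe_pwms = [p for p in pwms if p.family_id == cfg.mask_oe_family]
            tata_pwms = [p for p in pwms if p.family_id == cfg.mask_tata_family]
            oe_hits = scan_sequences(promoters, oe_pwms, "opt-0.1") if oe_pwms else []
            tata_hits = scan_sequences(promoters, tata_pwms, "opt") if tata_pwms else []
            mask = msk.build_mask(oe_hits, tata_hits, cfg.tata_window)
            if outdir is not None:
                mask.to_bed(outdir / "mask.bed")

            for mode in cfg.threshold_modes:
                stage = f"post-mask analysis ({mode})"
                table = analyze_dataset(promoters, pwms, mode, cfg.B, cfg.seed,
                                        tracks=tracks, mask=mask,
                                        strict_shuffle=cfg.strict_shuffle)
                table, venn = summarize(table, cfg.alpha, m)
                out["postmask"][mode] = table
                out["postmask_venn"][mode] = venn
                if outdir is not None:
                    table.to_csv(outdir / f"report_postmask_{_slug(mode)}.tsv",
                                 sep="\t", index=False)
            out["mask"] = mask
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    if outdir is not None:
        log = {"seed": cfg.seed, "B": cfg.B, "m": m,
               "n_promoters": len(promoters), "n_families": n_families,
               "premask_venn": out["premask_venn"],
               "postmask_venn": out["postmask_venn"]}
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return out


def _slug(mode: str) -> str:
    return mode.replace("-", "_").replace(".", "")


def null_calibration_study(n_promoters: int = 150, n_decoys: int = 50,
                           B: int = 1000, seed: int = 0,
                           mode: str = "opt") -> dict:
    """Type-I calibration on fully null synthetic promoters.

    Simulates promoters with no planted motifs, runs all three tests
    against *n_decoys* decoy families, and counts families significant
    in all three at the Bonferroni level.  Under the null this count
    should be (almost always) zero.
    """
    from promoscan.simulate import SimConfig, make_decoy_pwms, simulate_promoters
    from promoscan.simulate import simulate_conservation

    pwms = make_decoy_pwms(n_decoys, seed=seed + 1)
    cfg = SimConfig(n_promoters=n_promoters, planted=[], seed=seed)
    promoters, _ = simulate_promoters(cfg)
    tracks = simulate_conservation([], promoters.ids, cfg.L, boost=0.0,
                                   seed=seed + 2)
    table = analyze_dataset(promoters, pwms, mode, B, seed + 3, tracks=tracks)
    table, venn = summarize(table, 0.05, m=n_decoys)
    return {"table": table, "venn": venn,
            "n_triple_significant": venn["binomial+shuffle+conservation"]}


def parameter_recovery_study(n_promoters: int = 300, n_decoys: int = 50,
                             B: int = 1000, mean_sites: float = 1.4,
                             boost: float = 0.4, seed: int = 0,
                             mode: str = "opt") -> dict:
    """End-to-end recovery of one planted 21-bp motif.

    Plants the O/E-like demonstration matrix at *mean_sites* per
    promoter with a TSS-proximal positional bias and a conservation
    boost inside sites, runs the three tests against decoy families,
    and re-scans after masking the planted family's relaxed-stringency
    extents.  Reports the planted family's row, whether it is
    Bonferroni-significant in all three tests, the number of
    triple-significant decoys, and the post-mask hit count (expected
    zero).
    """
    from promoscan.simulate import (PlantSpec, SimConfig, make_decoy_pwms,
                                    make_oe_pwm, simulate_conservation,
                                    simulate_promoters)

    oe = make_oe_pwm()
    pwms = [oe] + make_decoy_pwms(n_decoys, seed=seed + 1)
    cfg = SimConfig(n_promoters=n_promoters,
                    planted=[PlantSpec(oe, mean_sites, ("gaussian", -75.0, 40.0))],
                    seed=seed)
    promoters, truth = simulate_promoters(cfg)
    tracks = simulate_conservation(truth, promoters.ids, cfg.L, boost=boost,
                                   seed=seed + 2)
    table = analyze_dataset(promoters, pwms, mode, B, seed + 3, tracks=tracks)
    table, venn = summarize(table, 0.05, m=n_decoys + 1)

    bonf = enr.bonferroni_threshold(0.05, n_decoys + 1)
    row = table.set_index("family_id").loc[oe.family_id]
    planted_triple = bool(
        row["p_binomial"] < bonf and row["p_shuffle"] < bonf
        and min(row["p_cons_whole"], row["p_cons_core"]) < bonf)
    decoy_triple = venn["binomial+shuffle+conservation"] - int(planted_triple)

    raw = scan_sequences(promoters, [oe], "opt-0.1")
    mask = msk.build_mask(raw)
    masked = msk.mask_promoter_set(mask, promoters)
    postmask_hits = len(scan_sequences(masked, [oe], "opt-0.1"))
    return {"table": table, "venn": venn, "planted_family": oe.family_id,
            "planted_row": row, "planted_triple_significant": planted_triple,
            "n_decoys_triple_significant": decoy_triple,
            "postmask_planted_hits": postmask_hits,
            "n_planted_sites": len(truth)}


def annotate_expression(report: pd.DataFrame, expr_table, symbol_map: dict,
                        min_fpkm: float = 10.0) -> pd.DataFrame:
    """Join factor expression onto the report.

    *expr_table* is a DataFrame indexed by gene symbol with one column
    per cell type (or a TSV path with a ``symbol`` column);
    *symbol_map* maps family/matrix ids to gene symbols.  A family is
    flagged "expressed" when any cell type reaches *min_fpkm*; symbols
    absent from the table get "no data".  Duplicate symbols take the
    maximum fpkm with a warning.
    """
    import warnings

    if not isinstance(expr_table, pd.DataFrame):
        expr_table = pd.read_csv(expr_table, sep="\t")
    if "symbol" in expr_table.columns:
        expr_table = expr_table.set_index("symbol")
    if expr_table.shape[1] < 1:
        raise ValueError("expression table needs at least one cell-type column")
    if expr_table.index.has_duplicates:
        warnings.warn("duplicate symbols in expression table; taking max fpkm")
        expr_table = expr_table.groupby(level=0).max()

    out = report.copy()
    symbols, status, max_fpkm = [], [], []
    for fam in out["family_id"]:
        sym = symbol_map.get(fam)
        symbols.append(sym if sym else "")
        if sym is None or sym not in expr_table.index:
            status.append("no data")
            max_fpkm.append(float("nan"))
            continue
        peak = float(expr_table.loc[sym].max())
        max_fpkm.append(peak)
        status.append("expressed" if peak >= min_fpkm else "not expressed")
    out["symbol"] = symbols
    out["max_fpkm"] = max_fpkm
    out["expression"] = status
    return out
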