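"""End-to-end orchestration: screen -> trim -> model selection -> ML + bootstrap
-> constrained tests -> composition, with reproducible reports.

Every report carries the tool version, the seed and the selected model, and a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import TrimConfig, cull_gappy_sequences, read_fasta, read_fasta_alignment
from .composition import (
    CodingSequence,
    CodonUsageTable,
    build_gc_distribution,
    classify_gc,
    codon_adaptation_test,
    gc_content,
)
from .hgt import TaxonomyMap, build_constraints, hgt_model_test, hgt_verdict, read_constraint_spec
from .screen import ScreenConfig, filter_hits, read_hit_table, read_taxonomy_tsv, select_representatives
from .search import ConstraintSet, SearchConfig, bootstrap_support, nj_start_tree, nni_search
from .selection import EVIDENCE_THRESHOLD, select_best_model
from .substmodels import parse_model_spec

log = logging.getLogger("hgtscreen")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, completed: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause} (completed: {completed})")
        self.stage = stage
        self.completed = completed


@dataclass(frozen=True)
class PipelineConfig:
    alignment: str = ""
    taxonomy: str = ""
    constraints: str = ""        # optional constraint spec file
    hits: str = ""               # optional BLAST outfmt-6 file
    cds: str = ""                # optional FASTA of focal coding sequences
    recipient_cds: str = ""      # FASTA defining the recipient %GC distribution
    donor_cds: str = ""          # FASTA defining the donor %GC distribution
    recipient_usage: str = ""    # codon-usage TSVs for CAI
    donor_usage: str = ""
    out_dir: str = "hgtscreen_out"
    candidate_models: tuple = ("LG", "LG+G", "WAG", "WAG+G", "JTT+G")
    evidence_threshold: float = EVIDENCE_THRESHOLD
    n_bootstrap: int = 100
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        screen_kw = raw.pop("screen", {})
        if "reps_per_group" in screen_kw:
            screen_kw["reps_per_group"] = tuple(screen_kw["reps_per_group"])
        if "unlimited_groups" in screen_kw:
            screen_kw["unlimited_groups"] = frozenset(screen_kw["unlimited_groups"])
        trim_kw = raw.pop("trim", {})
        if "candidate_models" in raw:
            raw["candidate_models"] = tuple(raw["candidate_models"])
        return cls(
            screen=ScreenConfig(**screen_kw), trim=TrimConfig(**trim_kw), **raw
        )


def _header(cfg: PipelineConfig, extra: dict | None = None) -> list[str]:
    lines = [f"# hgtscreen {__version__}", f"# seed={cfg.seed}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def run_hgt_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the machine-readable summary.

    Writes per-stage artifacts into ``cfg.out_dir``.  Any stage error aborts
    with the stage name and the artifacts completed so far.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"tool": "hgtscreen", "version": __version__, "seed": cfg.seed}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                fn()
                completed.append(name)
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc, completed) from exc

        return deco

    state: dict = {}

    if cfg.hits:
        @stage("screen")
        def _screen():
            hits = filter_hits(read_hit_table(cfg.hits), cfg.screen)
            taxonomy = read_taxonomy_tsv(cfg.taxonomy)
            ids = select_representatives(hits, taxonomy, cfg.screen)
            with open(out / "selected_ids.txt", "w") as fh:
                fh.write("\n".join(ids) + "\n")
            state["selected_ids"] = ids
            summary["n_selected"] = len(ids)

    @stage("trim")
    def _trim():
        aln = read_fasta_alignment(cfg.alignment)
        if "selected_ids" in state:
            keep = [i for i in aln.ids if i in set(state["selected_ids"])]
            if len(keep) >= 3:
                aln = aln.subset(keep).drop_allgap_columns()
        from .alignment import core_gap_report

        report = dict(core_gap_report(aln, cfg.trim))
        trimmed, removed, recompute = cull_gappy_sequences(aln, cfg.trim)
        trimmed.write(out / "trimmed.fasta")
        with open(out / "removal_report.tsv", "w") as fh:
            fh.write("\n".join(_header(cfg)) + "\n")
            fh.write("id\tcore_gap_fraction\tremoved\n")
            for sid in aln.ids:
                fh.write(
                    f"{sid}\t{report[sid]:.4f}\t{'yes' if sid in removed else 'no'}\n"
                )
        state["aln"] = trimmed
        summary["n_sequences"] = trimmed.n_sequences
        summary["n_sites"] = trimmed.n_sites
        summary["removed"] = removed
        summary["realignment_recommended"] = recompute

    @stage("model_selection")
    def _select():
        aln = state["aln"]
        start = nj_start_tree(aln)
        cands = [parse_model_spec(s) for s in cfg.candidate_models]
        fits = select_best_model(aln, start, cands)
        with open(out / "model_selection.tsv", "w") as fh:
            fh.write("\n".join(_header(cfg)) + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["Rank", "Model", "K", "lnL", "BIC", "AICc"])
            for i, f in enumerate(fits, 1):
                w.writerow([i, f.model.label, f.K, f"{f.lnL:.4f}", f"{f.BIC:.4f}", f"{f.AICc:.4f}"])
        state["model"] = fits[0].model
        state["start"] = start
        summary["model"] = fits[0].model.label
        summary["K"] = fits[0].K

    @stage("tree_inference")
    def _tree():
        aln, model = state["aln"], state["model"]
        scfg = SearchConfig(n_bootstrap=cfg.n_bootstrap, seed=cfg.seed)
        best, lnl = nni_search(aln, model, state["start"], scfg)
        with_support = bootstrap_support(aln, model, scfg, best_tree=best)
        with_support.write(out / "ml_tree.nwk", support=True)
        state["ml_tree"] = with_support
        state["search_cfg"] = scfg
        summary["lnL"] = round(lnl, 4)

    @stage("hgt_test")
    def _test():
        aln, model = state["aln"], state["model"]
        taxmap = TaxonomyMap.read_tsv(cfg.taxonomy)
        taxmap.check_covers(aln.ids)
        if cfg.constraints:
            entries = read_constraint_spec(cfg.constraints)
            sets = [
                e if isinstance(e, ConstraintSet) else build_constraints(taxmap, [e])[0]
                for e in entries
            ]
        else:
            from .hgt import taxonomy_constraint

            sets = [taxonomy_constraint(taxmap, aln.ids)]
        comp = hgt_model_test(
            aln, model, sets, state["search_cfg"], threshold=cfg.evidence_threshold
        )
        with open(out / "comparison.tsv", "w") as fh:
            fh.write("\n".join(_header(cfg, {"model": model.label})) + "\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["Rank", "Constraint", "Sub. Model", "K", "dBIC", "dAICc", "Verdict"])
            for row in comp.to_table():
                w.writerow(
                    [row["Rank"], row["Constraint"], row["Sub. Model"], row["K"],
                     f"{row['dBIC']:.3f}", f"{row['dAICc']:.3f}", row["Verdict"]]
                )
        summary["hgt_verdict"] = hgt_verdict(comp, cfg.evidence_threshold)
        summary["comparison"] = [
            {"constraint": r.label, "dBIC": round(r.delta_bic, 3),
             "dAICc": round(r.delta_aicc, 3), "verdict": r.verdict}
            for r in comp.rows
        ]

    if cfg.cds and cfg.recipient_cds and cfg.donor_cds:
        @stage("composition")
        def _composition():
            focal = [CodingSequence(i, s) for i, s in read_fasta(cfg.cds).items()]
            rec = [CodingSequence(i, s) for i, s in read_fasta(cfg.recipient_cds).items()]
            don = [CodingSequence(i, s) for i, s in read_fasta(cfg.donor_cds).items()]
            rdist = build_gc_distribution(rec, "recipient")
            ddist = build_gc_distribution(don, "donor")
            r_usage = (
                CodonUsageTable.read_tsv(cfg.recipient_usage, "recipient")
                if cfg.recipient_usage
                else CodonUsageTable.from_cds_set(rec, "recipient")
            )
            d_usage = (
                CodonUsageTable.read_tsv(cfg.donor_usage, "donor")
                if cfg.donor_usage
                else CodonUsageTable.from_cds_set(don, "donor")
            )
            rows = []
            for cds in focal:
                gc = gc_content(cds)
                gc_class = classify_gc(gc, rdist, ddist)
                res_r, res_d = codon_adaptation_test(
                    cds, r_usage, d_usage, seed=cfg.seed
                )
                rows.append(
                    {"id": cds.id, "gc": round(gc, 3), "gc_class": gc_class,
                     "cai_recipient": round(res_r.cai, 4), "ecai_recipient": round(res_r.ecai, 4),
                     "cai_verdict_recipient": res_r.verdict,
                     "cai_donor": round(res_d.cai, 4), "ecai_donor": round(res_d.ecai, 4),
                     "cai_verdict_donor": res_d.verdict}
                )
            with open(out / "composition.tsv", "w") as fh:
                fh.write("\n".join(_header(cfg)) + "\n")
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(list(rows[0].keys()))
                for r in rows:
                    w.writerow(list(r.values()))
            summary["composition"] = rows

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def setup_logging(logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO, format="%(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True,
    )
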