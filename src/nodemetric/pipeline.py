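"""End-to-end study workflow orchestration.

The full analysis runs in stages: ingest (or simulate) a cohort table,
annotate intra-patient ratios, build the sentinel and pooled analysis sets,
derive per-metric Youden-optimal cut-offs on the sentinel set (reader 1),
transfer-validate those fixed cut-offs on the pooled set (reader 1) and on
all nodes as measured by reader 2, and run the inter-reader agreement
suite. Every output table row carries its effective n and provenance
(set, reader, metric, cut-off source); a JSON run manifest records the
seed, stage logs and exclusion counts. Identical config + seed produce
identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort_stats as cs
from .data import (
    AnalysisSet,
    METRICS,
    Reader,
    SetName,
    TruthStatus,
    build_mln_set,
    build_sln_set,
    metric_values,
    n_exclusions,
    pivot_readers,
    read_cohort_table,
    write_cohort_table,
)
from .performance import (
    CutoffResult,
    auc_ci,
    classify_at_cutoff,
    default_orientation,
    logistic_fit_single,
    roc_curve,
    round_half_up,
    transfer_validation,
    youden_optimal_cutoff,
)
from .ratios import annotate_ratios
from .simulate import default_config, generate_cohort

__all__ = [
    "RunConfig",
    "prepare_cohort",
    "run_derivation",
    "run_transfer",
    "run_agreement",
    "run_all",
]

log = logging.getLogger("nodemetric")

DEFAULT_METRICS = tuple(METRICS)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None  # None -> simulate a cohort
    metrics: tuple[str, ...] = DEFAULT_METRICS
    derivation_set: str = "SLN_SET"
    validation_sets: tuple[tuple[str, str], ...] = (
        ("MLN_SET", "R1"),
        ("ALL_LNS", "R2"),
    )
    ci_method: str = "delong"
    n_boot: int = 2000
    rounding: int = 2
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.derivation_set not in ("SLN_SET", "MLN_SET", "ALL_LNS"):
            raise ValueError(f"unknown derivation set {self.derivation_set!r}")


def _all_lns_set(records) -> AnalysisSet:
    aset = AnalysisSet(SetName.ALL_LNS, list(records), [])
    aset.provenance_log.append(
        f"all-LNs set: {aset.n_nodes} nodes ({aset.n_pos} metastatic, "
        f"{aset.n_neg} benign)"
    )
    return aset


def prepare_cohort(config: RunConfig):
    """Ingest or simulate, annotate ratios, build the three analysis sets.

    Returns ``(records, panels, sets, manifest)`` where ``sets`` maps set
    name to :class:`AnalysisSet`.
    """
    config.validate()
    manifest = {"seed": config.seed, "stages": []}
    if config.input_path is None:
        cfg = default_config(seed=config.seed)
        records, panels, _ = generate_cohort(cfg)
        manifest["stages"].append(
            {"stage": "simulate", "n_records": len(records), "seed": config.seed}
        )
        log.info("[simulate] generated %d records", len(records))
    else:
        table = read_cohort_table(config.input_path)
        records, panels = table.records, table.panels
        manifest["stages"].append(
            {
                "stage": "ingest",
                "path": str(config.input_path),
                "n_records": len(records),
                "diagnostics": table.diagnostics,
            }
        )
        log.info("[ingest] read %d records from %s", len(records), config.input_path)

    diags = annotate_ratios(records, panels)
    manifest["stages"].append({"stage": "ratios", "diagnostics": diags})

    sln = build_sln_set(records)
    mln = build_mln_set(records)
    alln = _all_lns_set(records)
    for aset in (sln, mln, alln):
        manifest["stages"].append(
            {
                "stage": f"build_{aset.name.value.lower()}",
                "n_nodes": aset.n_nodes,
                "n_pos": aset.n_pos,
                "n_neg": aset.n_neg,
                "n_excluded": n_exclusions(aset),
                "log": aset.provenance_log,
            }
        )
        log.info(
            "[sets] %s: %d nodes (%d/%d), %d excluded",
            aset.name.value, aset.n_nodes, aset.n_pos, aset.n_neg, n_exclusions(aset),
        )
    sets = {"SLN_SET": sln, "MLN_SET": mln, "ALL_LNS": alln}
    return records, panels, sets, manifest


def _metric_arrays(aset: AnalysisSet, metric: str, reader: Reader):
    vals, labels = [], []
    n_absent = 0
    for r in aset.reader_records(reader):
        v = metric_values(r, metric)
        if v is None:
            n_absent += 1
        else:
            vals.append(v)
            labels.append(r.truth_status)
    return np.asarray(vals, float), labels, n_absent


def run_derivation(
    aset: AnalysisSet,
    metrics=DEFAULT_METRICS,
    reader: Reader = Reader.R1,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, CutoffResult]]:
    """Per-metric ROC, AUC + CI, Youden cut-off, performance at the cut-off
    and single-predictor logistic McFadden R^2, on one set and reader."""
    rows, cutoffs = [], {}
    for metric in metrics:
        vals, labels, n_absent = _metric_arrays(aset, metric, reader)
        orientation = default_orientation(metric)
        roc = roc_curve(vals, labels, orientation)
        ci = auc_ci(roc, method=ci_method, n_boot=n_boot, seed=seed)
        cut = youden_optimal_cutoff(roc)
        cutoffs[metric] = cut
        fit = logistic_fit_single(vals, labels)
        preds = classify_at_cutoff(vals, cut.cutoff, orientation)
        pos = [lab is TruthStatus.METASTATIC for lab in labels]
        tp = sum(1 for p, t in zip(preds, pos) if p and t)
        fp = sum(1 for p, t in zip(preds, pos) if p and not t)
        rows.append(
            {
                "set": aset.name.value,
                "reader": reader.value,
                "metric": metric,
                "cutoff": cut.cutoff,
                "auc": roc.auc,
                "ci_l": ci[0],
                "ci_u": ci[1],
                "acc": (tp + (roc.n_neg - fp)) / (roc.n_pos + roc.n_neg),
                "sens": cut.sens_at_cutoff,
                "spec": cut.spec_at_cutoff,
                "ppv": tp / (tp + fp) if tp + fp else float("nan"),
                "npv": (roc.n_neg - fp) / (roc.n_neg - fp + roc.n_pos - tp)
                if roc.n_neg - fp + roc.n_pos - tp
                else float("nan"),
                "r2_mcfadden": fit.mcfadden_r2,
                "youden_j": cut.youden_j,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "effective_n": roc.n_pos + roc.n_neg,
                "n_absent": n_absent,
                "separation_flag": fit.separation,
            }
        )
        log.info(
            "[derive] %s/%s %s: cutoff=%.4g AUC=%.3f J=%.3f",
            aset.name.value, reader.value, metric, cut.cutoff, roc.auc, cut.youden_j,
        )
    return pd.DataFrame(rows), cutoffs


def run_transfer(
    target_sets: list[tuple[str, AnalysisSet, Reader]],
    cutoffs: dict[str, CutoffResult],
    cutoff_source: str = "SLN_SET/R1",
) -> pd.DataFrame:
    """Validate fixed, externally derived cut-offs on target sets.

    ``target_sets`` is a list of (label, set, reader); every metric with an
    available cut-off is evaluated on every target."""
    rows = []
    for label, aset, reader in target_sets:
        for metric, cut in cutoffs.items():
            try:
                cm, perf = transfer_validation(cut, aset, metric, reader=reader)
            except ValueError as err:
                log.warning("[transfer] %s %s skipped: %s", label, metric, err)
                continue
            rows.append(
                {
                    "target_set": label,
                    "reader": reader.value,
                    "metric": metric,
                    "cutoff": cut.cutoff,
                    "cutoff_source": cutoff_source,
                    "tp": cm.tp,
                    "tn": cm.tn,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "sens": perf.sens,
                    "spec": perf.spec,
                    "ppv": perf.ppv,
                    "npv": perf.npv,
                    "acc": perf.acc,
                    "youden_j": perf.youden_j,
                    "effective_n": perf.effective_n,
                    "n_absent": cm.n_excluded_absent,
                }
            )
            log.info(
                "[transfer] %s/%s %s @%.4g: acc=%.3f J=%s",
                label, reader.value, metric, cut.cutoff, perf.acc,
                None if perf.youden_j is None else f"{perf.youden_j:.3f}",
            )
    return pd.DataFrame(rows)


def run_agreement(
    records,
    metrics=DEFAULT_METRICS,
    cutoffs: dict[str, CutoffResult] | None = None,
) -> pd.DataFrame:
    """Inter-reader reliability per metric across all nodes.

    Per metric: per-reader median/IQR, per-reader metastatic-vs-benign
    Mann-Whitney p, ICC(2,1) with CI, Bland-Altman bias and limits of
    agreement (R1 - R2), and — when cut-offs are supplied —
    classification-vs-truth Gwet AC1 per reader at the fixed cut-off.
    """
    readers = {r.reader for r in records}
    if len(readers) < 2:
        raise ValueError("agreement analysis requires measurements by both readers")
    rows = []
    for metric in metrics:
        try:
            wide = pivot_readers(records, metric)
        except ValueError as err:
            log.warning("[agreement] %s skipped: %s", metric, err)
            continue
        if len(wide) < 3:
            log.warning("[agreement] %s skipped: <3 complete pairs", metric)
            continue
        x1 = wide["R1"].to_numpy(float)
        x2 = wide["R2"].to_numpy(float)
        pos = (wide["truth_status"] == TruthStatus.METASTATIC.value).to_numpy()
        icc = agr.icc_2_1(np.column_stack([x1, x2]))
        ba = agr.bland_altman(x1, x2)
        row = {
            "metric": metric,
            "n_pairs": icc.n_pairs,
            "n_dropped": wide.attrs.get("n_dropped", 0),
            "icc21": icc.estimate,
            "icc21_ci_l": icc.ci[0],
            "icc21_ci_u": icc.ci[1],
            "bias": ba.extras["bias"],
            "loa_lower": ba.extras["loa_lower"],
            "loa_upper": ba.extras["loa_upper"],
        }
        for rd, x in (("R1", x1), ("R2", x2)):
            med, q1, q3 = cs.median_iqr(x)
            row[f"{rd}_median"] = med
            row[f"{rd}_q1"] = q1
            row[f"{rd}_q3"] = q3
            if pos.any() and (~pos).any():
                _, p = cs.mann_whitney_u(x[pos], x[~pos])
            else:
                p = float("nan")
            row[f"{rd}_p_pos_vs_neg"] = p
        if cutoffs and metric in cutoffs:
            cut = cutoffs[metric]
            for rd, x in (("R1", x1), ("R2", x2)):
                preds = classify_at_cutoff(x, cut.cutoff, cut.orientation)
                ac1 = agr.gwet_ac1(pos, [bool(p) for p in preds])
                row[f"{rd}_ac1_vs_truth"] = ac1.estimate
                row[f"{rd}_ac1_ci_l"] = ac1.ci[0]
                row[f"{rd}_ac1_ci_u"] = ac1.ci[1]
        rows.append(row)
        log.info(
            "[agreement] %s: ICC=%.3f bias=%.4g LoA=(%.4g, %.4g)",
            metric, icc.estimate, row["bias"], row["loa_lower"], row["loa_upper"],
        )
    return pd.DataFrame(rows)


def _rounded(df: pd.DataFrame, ndigits: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda x: round_half_up(x, ndigits) if pd.notna(x) else x
            )
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns all result tables and the manifest.

    When ``config.outdir`` is set, writes cohort.csv, derivation.csv,
    transfer.csv, agreement.csv (raw and print-rounded copies) and
    manifest.json there.
    """
    records, panels, sets, manifest = prepare_cohort(config)
    derivation, cutoffs = run_derivation(
        sets[config.derivation_set],
        metrics=config.metrics,
        reader=Reader.R1,
        ci_method=config.ci_method,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    targets = [
        (name, sets[name], Reader(reader)) for name, reader in config.validation_sets
    ]
    targets.append((f"{config.derivation_set}:self", sets[config.derivation_set], Reader.R1))
    transfer = run_transfer(
        targets, cutoffs, cutoff_source=f"{config.derivation_set}/R1"
    )
    agreement_df = run_agreement(records, metrics=config.metrics, cutoffs=cutoffs)

    manifest["cutoffs"] = {
        m: {"cutoff": c.cutoff, "youden_j": c.youden_j} for m, c in cutoffs.items()
    }
    results = {
        "derivation": derivation,
        "transfer": transfer,
        "agreement": agreement_df,
        "manifest": manifest,
        "sets": sets,
        "records": records,
        "panels": panels,
    }
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(records, panels, outdir / "cohort.csv")
        for name in ("derivation", "transfer", "agreement"):
            results[name].to_csv(outdir / f"{name}.csv", index=False)
            _rounded(results[name], config.rounding).to_csv(
                outdir / f"{name}_rounded.csv", index=False
            )
        (outdir / "manifest.json").write_text(
            json.dumps(
                {**manifest, "config": dataclasses.asdict(config)},
                indent=2,
                default=str,
            )
        )
        log.info("[report] wrote results to %s", outdir)
    return results
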