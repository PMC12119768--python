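"""End-to-end orchestration: scoring -> classification -> evaluation -> curves.

``run_analysis`` takes a cohort (a :class:`~asdscreen.synthetic.CohortDataset`
or a CSV path in the long schema) and produces an :class:`AnalysisReport`:
per-wave prevalences, predictive-value tables for every outcome definition
(full threshold, Majority, Six Plus, any) overall and by intensity stratum,
ROC/Youden summaries, probit fits for the diagnosis-only and
diagnosis-plus-score models, and model-based PPV/NPV curve tables.  Every
percentage in the report is recomputable from the stored integer confusion
matrices, and the report carries the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .instruments import (
    DEFAULT_ASDS_CUTOFF,
    DEFAULT_SYMPTOM_MAP,
    SubjectRecord,
    SymptomMap,
    classify_wave,
    read_cohort_csv,
)
from .prediction import (
    PerfectSeparationError,
    fit_probit,
    predictive_curves,
    roc,
    youden_select,
)
from .screen_eval import ConfusionMatrix, metrics, stratified_metrics

__all__ = ["AnalysisReport", "run_analysis"]

OUTCOME_COLUMNS = {
    "full": "ptsd_full",
    "majority": "ptsd_majority",
    "six_plus": "ptsd_six_plus",
    "any": "ptsd_any",
}


@dataclass
class AnalysisReport:
    """Structured analysis output; ``data`` is JSON-serialisable throughout."""

    data: dict[str, Any]
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True, **kwargs)

    def write(self, outdir: str | Path) -> None:
        """Serialise the report: JSON document, metric tables and curve CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        self.metric_table().to_csv(outdir / "predictive_values.csv", index=False)
        for key, df in self.curves.items():
            df.to_csv(outdir / f"curve_{key}.csv", index=False)
        pd.DataFrame(self.log).to_csv(outdir / "pipeline_log.csv", index=False)

    def metric_table(self) -> pd.DataFrame:
        """Long-format analogue of the published predictive-value tables.

        One row per wave x outcome definition x metric, with the marginal
        ("any diagnosis") value and the low/high-intensity stratum values,
        percentages at 2 dp (half-up) alongside full-precision proportions.
        """
        from .screen_eval import round_half_up

        rows = []
        for wave, wdata in self.data["waves"].items():
            for outcome, odata in wdata.get("outcomes", {}).items():
                for metric in ("sensitivity", "specificity", "ppv", "npv"):
                    row = {"wave": wave, "outcome": outcome, "metric": metric}
                    marg = odata["marginal"]["metrics"][metric]
                    row["n"] = odata["marginal"]["metrics"][metric + "_denominator"]
                    row["any_diagnosis"] = (
                        None if marg is None else round_half_up(100 * marg, 2)
                    )
                    row["any_diagnosis_raw"] = marg
                    for stratum in ("low", "high"):
                        sdata = odata["strata"].get(stratum)
                        val = None if sdata is None else sdata["metrics"][metric]
                        row[f"{stratum}_intensity"] = (
                            None if val is None else round_half_up(100 * val, 2)
                        )
                        row[f"{stratum}_intensity_raw"] = val
                    rows.append(row)
        return pd.DataFrame(rows)


def _cm_dict(cm: ConfusionMatrix) -> dict[str, int]:
    return {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}


def _metrics_dict(cm: ConfusionMatrix) -> dict[str, Any]:
    ms = metrics(cm)
    out: dict[str, Any] = {}
    for name, est in (
        ("sensitivity", ms.sensitivity),
        ("specificity", ms.specificity),
        ("ppv", ms.ppv),
        ("npv", ms.npv),
    ):
        out[name] = est.value
        out[name + "_ci"] = [est.ci_low, est.ci_high]
        out[name + "_denominator"] = est.denominator
    return out


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_analysis(
    cohort: "Any",
    symptom_map: SymptomMap = DEFAULT_SYMPTOM_MAP,
    cutoff: int = DEFAULT_ASDS_CUTOFF,
    pcl5_threshold: int = 2,
    select_cutoff: bool = False,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full screening-evaluation pipeline on a cohort.

    Parameters
    ----------
    cohort : CohortDataset, list of SubjectRecord, or CSV path
    cutoff : int
        Intensity cut-off (default 58).  With ``select_cutoff=True`` the
        Youden-optimal cut-off from the wave's own ROC replaces it.
    """
    from .synthetic import CohortDataset

    log: list[dict] = []
    if isinstance(cohort, (str, Path)):
        records = read_cohort_csv(cohort)
        source = str(cohort)
    elif isinstance(cohort, CohortDataset):
        records = cohort.records
        source = f"synthetic(seed={cohort.seed}, v{cohort.generator_version})"
        if seed is None:
            seed = cohort.seed
    else:
        records = list(cohort)
        source = "records"
    log.append({"stage": "load", "n_in": len(records), "n_out": len(records)})

    tables = classify_wave(
        records, symptom_map=symptom_map, cutoff=cutoff, pcl5_threshold=pcl5_threshold
    )
    log.append(
        {
            "stage": "classify",
            "n_in": len(records),
            "n_out": len(tables.w1) + len(tables.w2),
            "excluded": len(tables.exclusions),
        }
    )

    data: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "source": source,
        "cutoff": cutoff,
        "config_hash": _config_hash(
            {
                "cutoff": cutoff,
                "pcl5_threshold": pcl5_threshold,
                "asds_threshold": symptom_map.endorsement_threshold,
                "select_cutoff": select_cutoff,
            }
        ),
        "exclusions": tables.exclusions.to_dict("records"),
        "waves": {},
    }
    curves: dict[str, pd.DataFrame] = {}

    for wave in ("W1", "W2"):
        df = tables.table(wave)
        wdata: dict[str, Any] = {"n": int(len(df))}
        if df.empty:
            wdata["available"] = False
            data["waves"][wave] = wdata
            log.append({"stage": f"evaluate_{wave}", "n_in": 0, "n_out": 0})
            continue
        wdata["available"] = True
        wdata["prevalence"] = {
            "asd": float(df["asd_diagnosis"].mean()),
            **{
                name: float(df[col].mean())
                for name, col in OUTCOME_COLUMNS.items()
            },
        }

        scores = df["asds_total"].to_numpy()
        diag = df["asd_diagnosis"].to_numpy()

        # cut-off selection against the full-threshold outcome
        y_full = df["ptsd_full"].to_numpy()
        wave_cutoff = cutoff
        if y_full.any() and not y_full.all():
            curve = roc(scores, y_full)
            sel = youden_select(curve)
            wdata["roc"] = {
                "auc": curve.auc,
                "auc_se": curve.auc_se,
                "auc_pvalue": curve.auc_pvalue,
                "youden_best_cutoff": sel.best_cutoff,
                "youden_best_j": sel.best_j,
                "youden_at": sel.compare(56, 58),
            }
            if select_cutoff:
                wave_cutoff = sel.best_cutoff
        wdata["cutoff_used"] = int(wave_cutoff)
        strata = np.where(scores >= wave_cutoff, "high", "low")
        wdata["stratum_sizes"] = {
            "low": int((strata == "low").sum()),
            "high": int((strata == "high").sum()),
        }

        wdata["outcomes"] = {}
        for outcome, col in OUTCOME_COLUMNS.items():
            y = df[col].to_numpy()
            table, per_stratum = stratified_metrics(diag, y, strata)
            odata: dict[str, Any] = {
                "marginal": {
                    "cm": _cm_dict(table.marginal),
                    "metrics": _metrics_dict(table.marginal),
                },
                "strata": {},
            }
            for label in ("low", "high"):
                cm = table.strata.get(label)
                if cm is None or cm.total == 0:
                    odata["strata"][label] = None
                    continue
                odata["strata"][label] = {
                    "cm": _cm_dict(cm),
                    "metrics": _metrics_dict(cm),
                }

            # probit models: (1) diagnosis only, (2) diagnosis + intensity
            n = len(df)
            X1 = np.column_stack([np.ones(n), diag.astype(float)])
            X2 = np.column_stack([np.ones(n), diag.astype(float), scores.astype(float)])
            for label, X, names in (
                ("probit_diagnosis", X1, ("intercept", "asd_diagnosis")),
                ("probit_diagnosis_score", X2, ("intercept", "asd_diagnosis", "asds_total")),
            ):
                try:
                    fit = fit_probit(X, y, names=names)
                    odata[label] = {
                        "coefficients": dict(zip(names, fit.coefficients.tolist())),
                        "se": dict(zip(names, fit.se().tolist())),
                        "log_likelihood": fit.log_likelihood,
                        "converged": fit.converged,
                        "n": fit.n_obs,
                    }
                except (PerfectSeparationError, ValueError) as exc:
                    odata[label] = {"error": str(exc)}
                    log.append(
                        {"stage": f"{label}_{wave}_{outcome}", "warning": str(exc)}
                    )
                    fit = None
                if label == "probit_diagnosis_score" and fit is not None and fit.converged:
                    pos = scores[diag]
                    neg = scores[~diag]
                    lo = int(min(pos.min() if pos.size else scores.min(),
                                 neg.min() if neg.size else scores.min()))
                    hi = int(max(pos.max() if pos.size else scores.max(),
                                 neg.max() if neg.size else scores.max()))
                    pc = predictive_curves(fit, (lo, hi))
                    curves[f"{wave}_{outcome}"] = pd.DataFrame(
                        {"s": pc.scores.astype(int), "ppv": pc.ppv, "npv": pc.npv}
                    )
                    odata["curve_range"] = {
                        "ppv": [float(pc.ppv[0]), float(pc.ppv[-1])],
                        "npv": [float(pc.npv[0]), float(pc.npv[-1])],
                    }
            wdata["outcomes"][outcome] = odata
        data["waves"][wave] = wdata
        log.append({"stage": f"evaluate_{wave}", "n_in": len(df), "n_out": len(df)})

    return AnalysisReport(data=data, curves=curves, log=log)
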