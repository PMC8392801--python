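"""Cohort-level orchestration: feature tables and the prognostic report.

The report mirrors the shape of a dissemination-feature study: for each of
the seven standardized features it carries the ROC AUC (with DeLong CI) for
the PFS and OS endpoints, a pairwise DeLong p-value matrix, the optimal
PFS-derived cutoff (reused for OS), sensitivity/specificity, Cohen's kappa
of the induced high/low groups against the Euclidean centroid feature as
reference, log-rank chi2/p, and univariable plus multivariable (with
high-MTV and poor-ECOG) Cox hazard ratios.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .metrics import DisseminationFeatures, PatientBody, compute_features
from .segmentation import build_lesion_set
from .survival import (
    binary_agreement_kappa,
    cox_ph,
    delong_compare,
    logrank_test,
    optimal_cutoff,
    roc_auc,
    sens_spec,
)
from .volumes import LabelMask, VoxelGrid

__all__ = [
    "FEATURES",
    "REFERENCE_FEATURE",
    "patient_features",
    "lesion_table",
    "survival_report",
    "write_csv",
    "write_json",
]

FEATURES = list(DisseminationFeatures.FEATURE_NAMES)
REFERENCE_FEATURE = "sdmax_euc"


def patient_features(
    grid: VoxelGrid,
    seeds: LabelMask,
    body: PatientBody,
    config: RunConfig | None = None,
) -> DisseminationFeatures:
    """Segment lesions and compute the dissemination features for one patient."""
    config = config or RunConfig()
    lesion_set = build_lesion_set(
        grid, seeds, fraction=config.threshold_fraction, connectivity=config.connectivity
    )
    return compute_features(
        lesion_set,
        body,
        centroid_weighting=config.centroid_weighting,
        tsp_mode=config.tsp_mode,
        tsp_metric=config.tsp_metric,
    )


def lesion_table(lesion_set) -> pd.DataFrame:
    """Per-lesion summary: label, SUVmax, volume (cm3), centroid (mm)."""
    rows = [
        {
            "label": l.label,
            "n_voxels": l.n_voxels,
            "suv_max": l.suv_max,
            "volume_ml": l.volume_ml,
            "centroid_x_mm": l.centroid[0],
            "centroid_y_mm": l.centroid[1],
            "centroid_z_mm": l.centroid[2],
        }
        for l in lesion_set.lesions
    ]
    return pd.DataFrame(rows)


def _endpoint_stats(
    df: pd.DataFrame,
    feature: str,
    cutoff: float,
    time_col: str,
    event_col: str,
    config: RunConfig,
) -> dict:
    """Log-rank + uni/multivariable Cox for one feature/endpoint at a cutoff."""
    time = df[time_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    high = (df[feature] > cutoff).astype(int)
    out: dict = {}
    if event.sum() == 0 or high.sum() in (0, len(high)):
        out["logrank_chi2"] = out["logrank_p"] = None
        out["univariable"] = out["multivariable"] = None
        return out
    chi2, p = logrank_test(time[high == 0], event[high == 0], time[high == 1], event[high == 1])
    out["logrank_chi2"], out["logrank_p"] = chi2, p

    work = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "high_feature": high,
            "high_mtv": (df["mtv_ml"] > config.mtv_threshold_ml).astype(int),
            "poor_ecog": (df["ecog"] >= config.ecog_threshold).astype(int),
        }
    )

    def _fit(covs: list[str]) -> dict | None:
        try:
            fit = cox_ph(work, "time", "event", covs, ties=config.ties)
        except ValueError:
            return None
        return {
            name: {
                "hr": float(fit.hr[i]),
                "ci_lower": float(fit.ci_lower[i]),
                "ci_upper": float(fit.ci_upper[i]),
                "p": float(fit.p[i]),
            }
            for i, name in enumerate(fit.covariates)
        } | {"converged": fit.converged}

    out["univariable"] = _fit(["high_feature"])
    out["multivariable"] = _fit(["high_feature", "high_mtv", "poor_ecog"])
    return out


def survival_report(df: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Full prognostic evaluation of the seven features on one cohort table.

    ``df`` needs columns: the seven feature names, mtv_ml, ecog,
    time_pfs/event_pfs and (optionally) time_os/event_os. Patients with any
    NaN feature are excluded (and counted). Returns a JSON-serializable dict.
    """
    config = config or RunConfig()
    features = [f for f in FEATURES if f in df.columns]
    if not features:
        raise ValueError("no feature columns found in cohort table")
    n_total = len(df)
    df = df.dropna(subset=features).reset_index(drop=True)
    report: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest,
        "n_patients": int(len(df)),
        "n_excluded_nan_features": int(n_total - len(df)),
        "features": {},
        "delong_pairwise_p_pfs": None,
    }

    has_os = "time_os" in df.columns and "event_os" in df.columns
    ev_pfs = df["event_pfs"].to_numpy(int)
    degenerate = ev_pfs.sum() == 0 or ev_pfs.sum() == len(ev_pfs)

    ref_groups = None
    for feature in features:
        scores = df[feature].to_numpy(float)
        entry: dict = {}
        if degenerate:
            entry["auc_pfs"] = entry["auc_os"] = None
            entry["cutoff"] = entry["se"] = entry["sp"] = entry["kappa_vs_reference"] = None
            entry["pfs"] = entry["os"] = None
            report["features"][feature] = entry
            continue
        auc = roc_auc(scores, ev_pfs)
        entry["auc_pfs"] = {
            "auc": auc.auc, "ci_lower": auc.ci_lower, "ci_upper": auc.ci_upper,
        }
        if has_os and df["event_os"].sum() > 0:
            auc_os = roc_auc(scores, df["event_os"].to_numpy(int))
            entry["auc_os"] = {
                "auc": auc_os.auc, "ci_lower": auc_os.ci_lower, "ci_upper": auc_os.ci_upper,
            }
        else:
            entry["auc_os"] = None

        # cutoff derived on PFS, reused for OS
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cutoff = optimal_cutoff(
                scores,
                df["time_pfs"].to_numpy(float),
                ev_pfs,
                method=config.cutoff_method,
            )
        entry["cutoff"] = float(cutoff)
        se, sp = sens_spec(scores, cutoff, ev_pfs)
        entry["se"], entry["sp"] = se, sp
        groups = (scores > cutoff).astype(int)
        if feature == REFERENCE_FEATURE:
            ref_groups = groups
        entry["high_group_n"] = int(groups.sum())
        entry["pfs"] = _endpoint_stats(df, feature, cutoff, "time_pfs", "event_pfs", config)
        entry["os"] = (
            _endpoint_stats(df, feature, cutoff, "time_os", "event_os", config)
            if has_os
            else None
        )
        report["features"][feature] = entry

    if not degenerate:
        if ref_groups is None and REFERENCE_FEATURE in report["features"]:
            ref_groups = (
                df[REFERENCE_FEATURE].to_numpy(float)
                > report["features"][REFERENCE_FEATURE]["cutoff"]
            ).astype(int)
        for feature in features:
            entry = report["features"][feature]
            if ref_groups is not None and entry.get("cutoff") is not None:
                groups = (df[feature].to_numpy(float) > entry["cutoff"]).astype(int)
                entry["kappa_vs_reference"] = binary_agreement_kappa(ref_groups, groups)
            else:
                entry["kappa_vs_reference"] = None
        # pairwise DeLong comparison matrix on the PFS outcome
        mat = {}
        for fa in features:
            row = {}
            for fb in features:
                if fa == fb:
                    row[fb] = 1.0
                else:
                    _, p = delong_compare(
                        df[fa].to_numpy(float), df[fb].to_numpy(float), ev_pfs
                    )
                    row[fb] = p
            mat[fa] = row
        report["delong_pairwise_p_pfs"] = mat
    return report


def _provenance_header(config: RunConfig) -> str:
    return f"# petdmax {__version__} config={config.digest}\n"


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """Write a CSV with a one-line provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
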