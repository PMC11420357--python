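"""End-to-end orchestration: cohort -> network -> phenogroups -> survival.

``run_pipeline`` chains the preprocessing transformers, the MDS lens, the
Mapper network, the phenogroup clusterer, and the survival/stats layer,
writing GraphML, assignment CSVs, KM/ARR/Cox tables and a JSON run report
of the stage counts. ``check_report_invariants`` holds the arithmetic that
every report must satisfy (patients in network = total - outliers; group
sizes minus double-assignments add back to the network size).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, stats as gstats, survival as surv
from .lens import MDSLens
from .mapper import MapperNetwork, write_edge_list, write_graphml
from .phenogroup import PhenogroupClusterer, assignments_to_frame

__all__ = [
    "RunConfig",
    "run_pipeline",
    "survival_tables",
    "check_report_invariants",
    "percentage",
]


def percentage(numerator: float, denominator: float, digits: int = 0) -> float:
    """Table-style percentage: 100 * n / d rounded to ``digits``."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, digits) if digits else round(
        100.0 * numerator / denominator
    )


def check_report_invariants(
    total_patients: int,
    outlier_patients: int,
    network_patients: int,
    phenogroup_sizes,
    doubly_assigned: int,
    triply_or_more: int = 0,
) -> None:
    """Arithmetic consistency of a run report's stage counts.

    Raises AssertionError when the counts do not add up: the network must
    hold total - outliers patients, and (by inclusion-exclusion, with no
    patient in three or more groups) the phenogroup sizes minus the
    doubly-assigned count must give back the network size.
    """
    assert total_patients - outlier_patients == network_patients, (
        f"{total_patients} - {outlier_patients} != {network_patients}"
    )
    if triply_or_more == 0:
        total = int(sum(phenogroup_sizes))
        assert total - doubly_assigned == network_patients, (
            f"sum(groups)={total} - double={doubly_assigned} != {network_patients}"
        )


@dataclass
class RunConfig:
    features_path: str
    survival_path: str
    output_dir: str
    missing_threshold: float = 0.40
    resolution: int = 29
    gain: float = 1.6
    equalized: bool = True
    cluster_histogram_bins: int = 10
    k_phenogroups: int = 5
    endpoint: str = "all_cause_death"
    covariate_set: str = "caption"
    arr_horizons: tuple = tuple(range(1, 13))
    seed: int = 0

    def validate(self):
        for p in (self.features_path, self.survival_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.endpoint not in ("all_cause_death", "composite"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.covariate_set not in surv.COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {self.covariate_set!r}")


def _endpoint_spec(name: str) -> surv.EndpointSpec:
    return surv.ALL_CAUSE_DEATH if name == "all_cause_death" else surv.COMPOSITE


def survival_tables(
    records: pd.DataFrame,
    group_rows: dict,
    endpoint: str = "all_cause_death",
    covariate_set: str = "caption",
    arr_horizons=tuple(range(1, 13)),
):
    """Per-phenogroup KM summaries, yearly ARR, and device-effect Cox fits.

    ``group_rows`` maps phenogroup label -> positional row indices into
    ``records``. Returns ``(km_df, arr_df, cox_df, groups_ran)`` where
    ``groups_ran`` counts the groups for which a two-arm comparison was
    possible and the Cox model converged.
    """
    spec = _endpoint_spec(endpoint)
    covs = surv.COVARIATE_SETS[covariate_set]
    km_rows, arr_frames, cox_rows = [], [], []
    groups_ran = 0
    for label in sorted(group_rows):
        sub = records.iloc[sorted(group_rows[label])]
        times, events = surv.apply_endpoint(sub, spec)
        by_dev = {}
        for dev in ("CRT-P", "CRT-D"):
            sel = (sub["device"] == dev).to_numpy()
            if sel.sum() >= 2 and events[sel].sum() >= 1:
                by_dev[dev] = surv.km_estimate(times[sel], events[sel])
        for dev, curve in by_dev.items():
            for horizon in (5.0, 10.0):
                if horizon <= curve.max_time:
                    km_rows.append({
                        "phenogroup": label, "device": dev,
                        "horizon_years": horizon,
                        "mortality_pct": 100 * (1 - curve.survival_at(horizon)),
                    })
        if len(by_dev) == 2:
            entries = surv.arr_table(by_dev["CRT-P"], by_dev["CRT-D"], arr_horizons)
            af = surv.arr_frame(entries)
            af.insert(0, "phenogroup", label)
            arr_frames.append(af)
            dev_flag = (sub["device"] == "CRT-D").astype(float)
            cov_df = pd.DataFrame({"device_crtd": dev_flag.to_numpy()})
            for c in covs:
                if c in sub.columns:
                    cov_df[c] = sub[c].astype(float).to_numpy()
            try:
                fit = surv.cox_fit(times, events, cov_df)
                cox_rows.append({
                    "phenogroup": label, "model": "multivariable",
                    "hr": fit.hazard_ratio("device_crtd"),
                    "ci_lo": fit.table.loc["device_crtd", "ci_lo"],
                    "ci_hi": fit.table.loc["device_crtd", "ci_hi"],
                    "p": fit.table.loc["device_crtd", "p"],
                    "n": fit.n, "events": fit.n_events,
                })
                groups_ran += 1
            except RuntimeError:
                pass
    km_df = pd.DataFrame(km_rows)
    arr_df = pd.concat(arr_frames) if arr_frames else pd.DataFrame()
    cox_df = pd.DataFrame(cox_rows)
    return km_df, arr_df, cox_df, groups_ran


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the JSON-serializable run report.

    Identical config (including seed) produces identical reports. Any
    stage failure removes partial outputs and re-raises with the stage
    name.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        features = pd.read_csv(cfg.features_path, index_col="patient_id")
        records = pd.read_csv(cfg.survival_path, index_col="patient_id")
        records = records.loc[features.index]

        stage = "preprocess"
        filt = preprocess.FeatureFilter(cfg.missing_threshold).fit(features)
        kept = filt.transform(features)
        clean = preprocess.ZScorer().fit_transform(
            preprocess.MeanImputer().fit_transform(kept)
        )

        stage = "lens"
        lens = MDSLens().fit(clean)

        stage = "mapper"
        net = MapperNetwork(
            cfg.resolution, cfg.gain, cfg.equalized, cfg.cluster_histogram_bins
        ).fit(lens.lens_, distance=lens.distance_)

        stage = "phenogroup"
        pheno = PhenogroupClusterer(cfg.k_phenogroups, seed=cfg.seed).fit(net.graph_)
        ids = np.asarray(features.index)
        assignments_to_frame(pheno.patient_labels_, ids).to_csv(
            out / "phenogroups.csv", index=False
        )
        mortality = records["event"].astype(float).to_numpy()
        write_graphml(
            net.graph_, out / "network.graphml", patient_ids=ids,
            node_values={"mortality": mortality},
        )
        write_edge_list(net.graph_, out / "edges.csv")

        stage = "survival"
        network_positions = sorted(pheno.patient_labels_)
        group_rows = {g.label: sorted(g.patient_set) for g in pheno.phenogroups_}
        km_df, arr_df, cox_df, groups_ran = survival_tables(
            records, group_rows, cfg.endpoint, cfg.covariate_set, cfg.arr_horizons
        )
        km_df.to_csv(out / "km_summary.csv", index=False)
        if len(arr_df):
            arr_df.to_csv(out / "arr_by_year.csv", index=False)
        cox_df.to_csv(out / "cox_device_effect.csv", index=False)

        stage = "report"
        sizes = [len(g.patient_set) for g in pheno.phenogroups_]
        n_multi = {
            k: sum(1 for labs in pheno.patient_labels_.values() if len(labs) == k)
            for k in (2, 3)
        }
        times_all, events_all = surv.apply_endpoint(records, _endpoint_spec(cfg.endpoint))
        med, iqr = surv.reverse_km(times_all, events_all)
        report = {
            "n_patients": int(len(features)),
            "n_features_input": int(features.shape[1]),
            "discarded_features": filt.discarded_features_,
            "n_features_used": int(clean.shape[1]),
            "n_nodes": int(net.n_nodes_),
            "n_edges": int(net.n_edges_),
            "n_outlier_patients": int(len(pheno.outlier_patients_)),
            "n_network_patients": int(len(network_positions)),
            "n_autogroups": int(pheno.n_autogroups_),
            "n_phenogroups": int(len(pheno.phenogroups_)),
            "phenogroup_sizes": [int(s) for s in sizes],
            "n_double_assigned": int(n_multi[2]),
            "n_triple_or_more": int(n_multi[3]),
            "median_followup_years": None if np.isnan(med) else float(med),
            "followup_iqr_years": [None if np.isnan(q) else float(q) for q in iqr],
            "survival_comparisons_run": groups_ran,
            "seed": cfg.seed,
        }
        check_report_invariants(
            report["n_patients"], report["n_outlier_patients"],
            report["n_network_patients"], report["phenogroup_sizes"],
            report["n_double_assigned"], report["n_triple_or_more"],
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
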