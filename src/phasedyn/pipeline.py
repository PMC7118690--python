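"""End-to-end orchestration: simulate/load -> prep -> IPS -> states ->
metastates -> trajectory -> group statistics, with stable file contracts.

Every run writes to its own directory: cleaned time courses, per-subject IPS
series, the state model (JSON + centroid matrix + label sequences),
temporal and metastate profiles, trajectory metrics, group-comparison
tables, a surrogate-control report, and a manifest listing every artifact
with a SHA-256 checksum. Deterministic stages reproduce bit-identically
from the same config and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, dynamics, ips, prep, stats, synthetic, trajectory
from .containers import IPSSeries, StateModel, TimecourseSet

log = logging.getLogger("phasedyn")

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "write_results"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str
    manifest: str | None = None  # cohort manifest CSV; None -> simulate
    synthetic_seed: int = 7
    n_subjects_per_group: int | None = None  # None -> generator default
    ips_band: tuple[float, float] = (0.01, 0.08)
    sfnc_band: tuple[float, float] = (0.01, 0.15)
    sfnc_order: int = 5
    k_range: tuple[int, int] = (2, 10)
    n_perm: int = 10_000
    n_boot: int = 1000
    cluster_seed: int = 0
    stats_seed: int = 0
    trim_edges: bool = False
    db_space: str = "raw"
    surrogates: bool = False

    def to_json(self) -> str:
        d = dict(self.__dict__)
        return json.dumps(d, indent=1, default=list)


def read_cohort(manifest_path: str | Path, tr: float = 2.0) -> list[TimecourseSet]:
    """Load a cohort from a manifest CSV.

    Required columns: ``subject_id``, ``group``, ``timecourse_path``;
    optional: ``motion_path``, ``age``, ``sex``, ``seed``. Unknown columns
    are ignored with a warning. Subjects may have unequal T.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "timecourse_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    known = required | {"motion_path", "age", "sex", "mfd", "seed"}
    unknown = set(df.columns) - known
    if unknown:
        log.warning("ignoring unknown manifest column(s): %s", sorted(unknown))
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dupes}")
    subjects = []
    for _, row in df.iterrows():
        path = manifest_path.parent / row["timecourse_path"]
        if not path.exists():
            raise FileNotFoundError(f"subject {row['subject_id']}: {path} not found")
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")
        motion = None
        if "motion_path" in df.columns and isinstance(row.get("motion_path"), str):
            motion = np.loadtxt(manifest_path.parent / row["motion_path"])
        covars = {
            k: float(row[k])
            for k in ("age", "sex", "mfd")
            if k in df.columns and np.isfinite(row.get(k, np.nan))
        }
        subjects.append(
            TimecourseSet(
                subject_id=str(row["subject_id"]),
                data=data,
                tr=tr,
                component_labels=labels,
                motion_params=motion,
                group=int(row["group"]),
                covariates=covars or None,
            )
        )
    return subjects


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(run_dir: str | Path, artifacts: dict[str, Path]) -> Path:
    """Write the artifact manifest (name, path, checksum). Returns its path."""
    run_dir = Path(run_dir)
    rows = ["artifact,path,sha256"]
    for name, path in sorted(artifacts.items()):
        rows.append(f"{name},{path.relative_to(run_dir)},{_sha256(path)}")
    manifest = run_dir / "run_manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def _write_ips(run_dir: Path, series: IPSSeries) -> Path:
    path = run_dir / "ips" / f"{series.subject_id}.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(f"{p}-{q}" for p, q in series.pair_index)
    np.savetxt(path, series.ips, delimiter="\t", header=header, comments="")
    return path


def _write_state_model(run_dir: Path, model: StateModel) -> dict[str, Path]:
    out = {}
    meta = {
        "k": model.k,
        "db_scores": {str(k): v for k, v in model.db_scores.items()},
        "embedding_dim": model.embedding_dim,
        "seed": model.seed,
        "pair_ordering": "row-major upper triangle",
    }
    p = run_dir / "state_model.json"
    p.write_text(json.dumps(meta, indent=1))
    out["state_model"] = p
    p = run_dir / "centroids.tsv"
    np.savetxt(p, model.centroids, delimiter="\t")
    out["centroids"] = p
    labels_dir = run_dir / "labels"
    labels_dir.mkdir(exist_ok=True)
    for sid in sorted({s for s, _ in model.sample_index}):
        lp = labels_dir / f"{sid}.txt"
        np.savetxt(lp, model.labels_for(sid), fmt="%d")
        out[f"labels_{sid}"] = lp
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    (run_dir / "run_config.json").write_text(config.to_json())
    artifacts["run_config"] = run_dir / "run_config.json"

    stage = "simulate/load"
    try:
        if config.manifest is None:
            syn = synthetic.default_config(seed=config.synthetic_seed)
            if config.n_subjects_per_group is not None:
                syn.n_subjects_per_group = config.n_subjects_per_group
            subjects, truth = synthetic.generate_cohort(syn)
            synthetic.write_cohort(
                subjects, truth, run_dir / "cohort", seed=config.synthetic_seed
            )
            artifacts["cohort_manifest"] = run_dir / "cohort" / "manifest.csv"
            artifacts["ground_truth"] = run_dir / "cohort" / "ground_truth.json"
        else:
            subjects = read_cohort(config.manifest)

        stage = "prep"
        low, high = config.ips_band
        cleaned = [
            prep.standard_prep(ts, low, high, trim_edges=config.trim_edges)
            for ts in subjects
        ]
        clean_dir = run_dir / "cleaned"
        clean_dir.mkdir(exist_ok=True)
        for ts in cleaned:
            p = clean_dir / f"{ts.subject_id}.tsv"
            np.savetxt(
                p,
                ts.data,
                delimiter="\t",
                header="\t".join(ts.component_labels),
                comments="",
            )
            artifacts[f"cleaned_{ts.subject_id}"] = p

        stage = "ips"
        ips_list = [
            ips.ips_series(ips.analytic_signal(ts), group=ts.group) for ts in cleaned
        ]
        for series in ips_list:
            artifacts[f"ips_{series.subject_id}"] = _write_ips(run_dir, series)

        stage = "cluster"
        model = clustering.fit_states(
            ips_list,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.cluster_seed,
            db_space=config.db_space,
        )
        artifacts.update(_write_state_model(run_dir, model))

        stage = "dynamics"
        tr = subjects[0].tr
        profiles = {
            s.subject_id: dynamics.summarize_sequence(
                model.labels_for(s.subject_id), model.k, tr
            )
            for s in subjects
        }
        mean_t = dynamics.mean_transition_matrix(list(profiles.values()))
        partition = dynamics.fiedler_bipartition(mean_t, centroids=model.centroids)
        partition.ms_profiles = dynamics.metastate_profiles(model, partition)
        _, coph, two_cut = dynamics.hierarchical_validate(mean_t)
        partition.cophenetic_coefficient = coph
        ms_rows = []
        for sid, _prof in profiles.items():
            ms_prof, ratios = dynamics.metastate_dynamics(
                model.labels_for(sid), partition, tr
            )
            ms_rows.append(
                {
                    "subject_id": sid,
                    "ms1_prevalence": ms_prof.prevalence[0],
                    "ms2_prevalence": ms_prof.prevalence[1],
                    "ms1_persistence": ms_prof.persistence[0],
                    "ms2_persistence": ms_prof.persistence[1],
                    "ms1_dwell": ms_prof.dwell[0],
                    "ms2_dwell": ms_prof.dwell[1],
                    **ratios,
                }
            )
        ms_df = pd.DataFrame(ms_rows)
        p = run_dir / "metastates.json"
        p.write_text(
            json.dumps(
                {
                    "partition": partition.partition.tolist(),
                    "fiedler_vector": partition.fiedler_vector.tolist(),
                    "cophenetic_coefficient": coph,
                    "hierarchical_two_cut": two_cut.tolist(),
                },
                indent=1,
            )
        )
        artifacts["metastates"] = p
        p = run_dir / "metastate_dynamics.csv"
        ms_df.to_csv(p, index=False)
        artifacts["metastate_dynamics"] = p

        stage = "trajectory"
        traj_rows = []
        for series, ts in zip(ips_list, subjects):
            m = trajectory.trajectory_metrics(series)
            traj_rows.append(
                {"subject_id": ts.subject_id, "group": ts.group, **m.as_dict()}
            )
        traj_df = pd.DataFrame(traj_rows)
        p = run_dir / "trajectory.csv"
        traj_df.to_csv(p, index=False)
        artifacts["trajectory"] = p

        stage = "stats"
        groups = {ts.subject_id: ts.group for ts in subjects}
        measure_df = ms_df.copy()
        measure_df["group"] = measure_df["subject_id"].map(groups)
        measure_df = measure_df.drop(columns=["subject_id"])
        comparison = stats.compare_groups(
            measure_df, n_perm=config.n_perm, seed=config.stats_seed
        )
        traj_measures = traj_df.drop(columns=["subject_id"])
        comparison_traj = stats.compare_groups(
            traj_measures, n_perm=config.n_perm, seed=config.stats_seed + 1000
        )
        p = run_dir / "group_comparison.csv"
        pd.concat([comparison, comparison_traj]).to_csv(p, index=False)
        artifacts["group_comparison"] = p

        if config.surrogates:
            stage = "surrogates"
            report = {}
            for offset, method in enumerate(("phase_shuffle", "circular_shift"), 1):
                rng = np.random.default_rng(config.cluster_seed + 7919 * offset)
                surr = [
                    clustering.make_surrogate(ts, method, rng) for ts in subjects
                ]
                surr_clean = [
                    prep.standard_prep(ts, low, high, trim_edges=config.trim_edges)
                    for ts in surr
                ]
                surr_ips = [
                    ips.ips_series(ips.analytic_signal(ts)) for ts in surr_clean
                ]
                surr_model = clustering.fit_states(
                    surr_ips,
                    k_range=range(config.k_range[0], config.k_range[1] + 1),
                    seed=config.cluster_seed,
                    db_space=config.db_space,
                )
                report[method] = {
                    "db_scores": {str(k): v for k, v in surr_model.db_scores.items()},
                    "selected_k": surr_model.k,
                    "centroid_dynamic_range": clustering.centroid_dynamic_range(
                        surr_model.centroids
                    ),
                }
            report["empirical"] = {
                "db_scores": {str(k): v for k, v in model.db_scores.items()},
                "selected_k": model.k,
                "centroid_dynamic_range": clustering.centroid_dynamic_range(
                    model.centroids
                ),
            }
            p = run_dir / "surrogate_report.json"
            p.write_text(json.dumps(report, indent=1))
            artifacts["surrogate_report"] = p
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    write_results(run_dir, artifacts)
    return run_dir
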