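"""Plain-text readers and writers for runs, manifests, matrices and panels.

Formats: parcellated runs as TSV (header row = region names, one row per
timepoint), RMS traces as single-column text, the run/session manifest and
ground-truth records as JSON, matrices and edge panels as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SESSIONS, Cohort, SubjectData
from .connectome import EdgePanel
from .preprocess import ParcellatedRun

__all__ = [
    "write_run",
    "read_run",
    "write_cohort",
    "load_cohort",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_label_matrix_tsv",
    "write_edge_panel",
    "read_edge_panel",
    "write_network_labels",
    "read_network_labels",
    "write_truth_json",
]

_NA = "NA"


def write_run(run: ParcellatedRun, timeseries_path, rms_path) -> None:
    df = pd.DataFrame(run.signal, columns=run.region_names)
    df.to_csv(timeseries_path, sep="\t", index=False, float_format="%.10g")
    np.savetxt(rms_path, run.rms, fmt="%.6g")


def read_run(timeseries_path, rms_path, tr_seconds: float) -> ParcellatedRun:
    df = pd.read_csv(timeseries_path, sep="\t", float_precision="round_trip")
    rms = np.loadtxt(rms_path, dtype=float, ndmin=1)
    return ParcellatedRun(
        signal=df.to_numpy(dtype=float),
        rms=rms,
        tr_seconds=tr_seconds,
        region_names=[str(c) for c in df.columns],
    )


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write every run plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tr = cohort.subjects[0].sessions[SESSIONS[0]][0].tr_seconds
    manifest: dict = {"tr_seconds": tr, "subjects": {}}
    for subject in cohort.subjects:
        entry: dict = {}
        for session in SESSIONS:
            files = []
            for idx, run in enumerate(subject.sessions[session], start=1):
                stem = f"{subject.subject_id}_ses{session}_run{idx}"
                ts_name = f"{stem}_timeseries.tsv"
                rms_name = f"{stem}_rms.txt"
                write_run(run, outdir / ts_name, outdir / rms_name)
                files.append({"timeseries": ts_name, "rms": rms_name})
            entry[str(session)] = files
        manifest["subjects"][subject.subject_id] = entry
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_cohort(manifest_path) -> Cohort:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    tr = float(manifest["tr_seconds"])
    subjects = []
    for sid in sorted(manifest["subjects"]):
        entry = manifest["subjects"][sid]
        subject = SubjectData(subject_id=sid)
        for session in SESSIONS:
            runs = [
                read_run(base / f["timeseries"], base / f["rms"], tr)
                for f in entry[str(session)]
            ]
            if not runs:
                raise ValueError(f"subject {sid} is missing session {session}")
            subject.sessions[session] = runs
        subjects.append(subject)
    return Cohort(subjects=subjects)


def write_matrix_tsv(values: np.ndarray, region_names: list[str], path) -> None:
    # 17 significant digits guarantee exact float round-trips
    df = pd.DataFrame(values, index=region_names, columns=region_names)
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep=_NA)


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA],
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_label_matrix_tsv(labels: np.ndarray, region_names: list[str], path) -> None:
    df = pd.DataFrame(labels, index=region_names, columns=region_names)
    df = df.where(pd.notna(df), _NA)
    df.to_csv(path, sep="\t")


def write_edge_panel(panel: EdgePanel, path) -> None:
    cols = [f"{i}_{j}" for i, j in panel.edge_index]
    df = pd.DataFrame(panel.values, index=panel.subject_ids, columns=cols)
    df.index.name = "subject"
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep=_NA)


def read_edge_panel(panel_path) -> EdgePanel:
    df = pd.read_csv(panel_path, sep="\t", index_col=0, na_values=[_NA],
                     float_precision="round_trip")
    pairs = np.array(
        [[int(a), int(b)] for a, b in (c.split("_") for c in df.columns)]
    )
    return EdgePanel(
        values=df.to_numpy(dtype=float),
        edge_index=pairs,
        subject_ids=[str(s) for s in df.index],
    )


def write_network_labels(labels: dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"region": list(labels), "network": [labels[r] for r in labels]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_network_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["region", "network"]:
        raise ValueError("network label table needs 'region' and 'network' columns")
    return dict(zip(df["region"].astype(str), df["network"].astype(str)))


def write_truth_json(truth, path) -> None:
    """Serialize a CohortTruth record (arrays as nested lists)."""
    payload = {
        "pop_corr": truth.pop_corr.tolist(),
        "edge_scale": truth.edge_scale.tolist(),
        "subject_latents": truth.subject_latents.tolist(),
        "session_latents": truth.session_latents.tolist(),
        "amplitudes": truth.amplitudes.tolist(),
        "spike_frames": {
            sid: {
                str(ses): [frames.tolist() for frames in runs]
                for ses, runs in sessions.items()
            }
            for sid, sessions in truth.spike_frames.items()
        },
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
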