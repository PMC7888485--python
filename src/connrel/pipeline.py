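"""End-to-end orchestration: cohort -> preprocessing -> connectomes -> ICC
-> networks -> strength -> threshold sweeps -> cross-mode comparison.

``run_full_analysis`` executes the whole analysis for each requested GSR
mode and writes a text-only bundle (TSV matrices, JSON summaries) plus a
provenance record.  Identical seed and configuration reproduce the bundle
byte for byte.  Motion flags depend only on the RMS traces, so scrubbing
decisions are shared by the GSR+ and GSR- branches by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .cohort import SESSIONS, Cohort
from .connectome import (
    ConnectivityMatrix,
    build_edge_panel,
    correlation_matrix,
    edge_strength,
    network_average_fc,
    node_average,
)
from .inference import spearman, wilcoxon_signed_rank
from .preprocess import preprocess_session, subject_passes_motion
from .reliability import EdgewiseICC, bin_icc_array, icc_two_session, summarize_icc
from .reliability import edgewise_icc as _edgewise_icc
from .synthetic import CohortSpec, generate_timeseries_cohort
from .thresholding import threshold_sweep
from .connectome import unvectorize_upper

__all__ = ["RunConfig", "run_full_analysis", "write_masks"]

logger = logging.getLogger("connrel.pipeline")


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run."""

    manifest: str | None = None
    sim: CohortSpec | None = None
    gsr_modes: tuple[bool, ...] = (False, True)
    hp_cutoff_hz: float = 0.008
    rms_threshold: float = 0.30
    max_flagged_fraction: float = 0.15
    min_subjects: int = 10
    bin_scheme: str = "cicchetti4"
    thresholds: list[float] | None = None
    subject_subset: list[str] | None = None
    network_labels: dict[str, str] | None = None
    outdir: str = "connrel_results"
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.gsr_modes:
            raise ValueError("at least one GSR mode is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            sim = d["sim"]
            sim["pop_corr"] = np.asarray(sim["pop_corr"]).tolist()
        d["gsr_modes"] = list(self.gsr_modes)
        return d


def _mode_name(gsr: bool) -> str:
    return "gsr-on" if gsr else "gsr-off"


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("outdir", None)  # where results land is not part of the analysis
    payload = json.dumps(d, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "connrel": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _flagged_fractions(cohort: Cohort, rms_threshold: float) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for subject in cohort.subjects:
        fracs = []
        for session in SESSIONS:
            for run in subject.sessions.get(session, []):
                fracs.append(float((run.rms > rms_threshold).mean()))
        out[subject.subject_id] = fracs
    return out


def _exclude_subjects(cohort: Cohort, config: RunConfig) -> tuple[Cohort, list[dict]]:
    exclusions: list[dict] = []
    kept = []
    fractions = _flagged_fractions(cohort, config.rms_threshold)
    for subject in cohort.subjects:
        missing = [s for s in SESSIONS if not subject.sessions.get(s)]
        if missing:
            exclusions.append(
                {"subject": subject.subject_id, "reason": f"missing session {missing}"}
            )
            logger.warning("excluding %s: missing sessions %s",
                           subject.subject_id, missing)
            continue
        if not subject_passes_motion(
            fractions[subject.subject_id], config.max_flagged_fraction
        ):
            worst = max(fractions[subject.subject_id])
            exclusions.append(
                {
                    "subject": subject.subject_id,
                    "reason": f"flagged fraction {worst:.4f} exceeds "
                    f"{config.max_flagged_fraction}",
                }
            )
            logger.warning("excluding %s: worst flagged fraction %.4f",
                           subject.subject_id, worst)
            continue
        kept.append(subject)
    if not kept:
        raise ValueError("empty cohort after motion exclusions")
    return Cohort(subjects=kept, truth=cohort.truth), exclusions


def _session_matrices(
    cohort: Cohort, gsr: bool, config: RunConfig
) -> dict[int, list[ConnectivityMatrix]]:
    out: dict[int, list[ConnectivityMatrix]] = {s: [] for s in SESSIONS}
    for subject in cohort.subjects:
        for session in SESSIONS:
            ts = preprocess_session(
                subject.sessions[session],
                gsr=gsr,
                hp_cutoff_hz=config.hp_cutoff_hz,
                rms_threshold=config.rms_threshold,
            )
            out[session].append(
                correlation_matrix(ts, subject.subject_id, session)
            )
    return out


def write_masks(
    results: EdgewiseICC,
    eidx: np.ndarray,
    region_names: list[str],
    outdir,
    scheme: str = "cicchetti4",
) -> dict[str, str]:
    """Write the reliability "masks": four symmetric region x region TSVs
    (ICC, CI lower, CI upper, bin label); the diagonal is marked NA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r = len(region_names)
    paths: dict[str, str] = {}
    for name, vec in (
        ("icc", results.icc),
        ("ci_lower", results.ci_lower),
        ("ci_upper", results.ci_upper),
    ):
        mat = unvectorize_upper(vec, r, diagonal=np.nan)
        path = outdir / f"edge_{name}.tsv"
        _io.write_matrix_tsv(mat, region_names, path)
        paths[name] = str(path)
    labels = results.bins(scheme)
    lab_mat = np.full((r, r), None, dtype=object)
    iu = np.triu_indices(r, k=1)
    lab_mat[iu] = labels
    lab_mat[(iu[1], iu[0])] = labels
    path = outdir / "edge_bin.tsv"
    _io.write_label_matrix_tsv(lab_mat, region_names, path)
    paths["bin"] = str(path)
    return paths


def _network_icc_table(
    matrices: dict[int, list[ConnectivityMatrix]],
    labels: dict[str, str],
    alpha: float,
) -> pd.DataFrame:
    networks = sorted(set(labels.values()))
    per_session = {}
    for session in SESSIONS:
        rows = [
            [network_average_fc(m, labels)[net] for net in networks]
            for m in matrices[session]
        ]
        per_session[session] = np.asarray(rows)
    res = icc_two_session(per_session[1], per_session[2], alpha=alpha)
    return pd.DataFrame(
        {
            "network": networks,
            "icc": res.icc,
            "ci_lower": res.ci_lower,
            "ci_upper": res.ci_upper,
            "bin4": bin_icc_array(res.icc, "cicchetti4"),
            "bin5": bin_icc_array(res.icc, "xingzuo5"),
        }
    )


def run_full_analysis(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run the complete analysis and write the output bundle.

    Returns a dictionary describing the bundle (paths plus headline
    numbers); every artifact is also written under ``config.outdir``.
    A pre-built ``cohort`` overrides the config's manifest/simulation source.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if config.manifest is not None:
            cohort = _io.load_cohort(config.manifest)
        elif config.sim is not None:
            cohort = generate_timeseries_cohort(config.sim)
        else:
            raise ValueError(
                "provide a manifest path, a simulation spec, or a cohort"
            )
    n_input = len(cohort.subjects)
    if config.subject_subset is not None:
        cohort = cohort.subset(list(config.subject_subset))
    n_subset = len(cohort.subjects)
    cohort, exclusions = _exclude_subjects(cohort, config)

    region_names = cohort.region_names
    thresholds = (
        None if config.thresholds is None else np.asarray(config.thresholds)
    )

    bundle: dict = {"modes": {}}
    edge_icc_by_mode: dict[str, EdgewiseICC] = {}
    for gsr in config.gsr_modes:
        mode = _mode_name(gsr)
        mode_dir = outdir / mode
        mode_dir.mkdir(parents=True, exist_ok=True)
        matrices = _session_matrices(cohort, gsr, config)
        panel_s1 = build_edge_panel(matrices[1])
        panel_s2 = build_edge_panel(matrices[2])
        res = _edgewise_icc(panel_s1, panel_s2, alpha=config.alpha)
        edge_icc_by_mode[mode] = res

        mask_paths = write_masks(
            res, panel_s1.edge_index, region_names, mode_dir, config.bin_scheme
        )
        node_icc = node_average(res.icc, panel_s1.edge_index, len(region_names))
        pd.DataFrame({"region": region_names, "node_mean_icc": node_icc}).to_csv(
            mode_dir / "node_icc.tsv", sep="\t", index=False,
            float_format="%.10g", na_rep="NA",
        )

        strength = edge_strength(panel_s1, panel_s2)
        ok = np.isfinite(strength) & np.isfinite(res.icc)
        strength_test = (
            spearman(strength[ok], res.icc[ok]).to_dict() if ok.sum() >= 3 else None
        )

        summary = {
            "gsr": gsr,
            "icc_summary": summarize_icc(res),
            "strength_vs_icc": strength_test,
        }
        (mode_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )

        if config.network_labels:
            table = _network_icc_table(
                matrices, config.network_labels, config.alpha
            )
            table.to_csv(mode_dir / "network_icc.tsv", sep="\t", index=False,
                         float_format="%.10g", na_rep="NA")

        sweep_info = {}
        for sweep_mode in ("absolute", "relative"):
            report = threshold_sweep(
                panel_s1,
                panel_s2,
                mode=sweep_mode,
                thresholds=thresholds,
                min_subjects=config.min_subjects,
                alpha=config.alpha,
                bin_scheme=config.bin_scheme,
            )
            (mode_dir / f"sweep_{sweep_mode}.json").write_text(
                json.dumps(report.to_dict(), indent=1, sort_keys=True)
            )
            report.per_threshold_frame().to_csv(
                mode_dir / f"sweep_{sweep_mode}.tsv", sep="\t", index=False,
                float_format="%.10g", na_rep="NA",
            )
            sweep_info[sweep_mode] = {
                "trend_consistency_rho": report.trend_consistency_rho,
                "trend_icc_rho": report.trend_icc_rho,
            }

        bundle["modes"][mode] = {
            "masks": mask_paths,
            "median_icc": summary["icc_summary"]["median"],
            "strength_vs_icc": strength_test,
            "sweeps": sweep_info,
        }

    if len(config.gsr_modes) >= 2 and {"gsr-on", "gsr-off"} <= set(
        edge_icc_by_mode
    ):
        on = edge_icc_by_mode["gsr-on"].icc
        off = edge_icc_by_mode["gsr-off"].icc
        ok = np.isfinite(on) & np.isfinite(off)
        outcome = wilcoxon_signed_rank(off[ok], on[ok])
        comparison = {
            "contrast": "gsr-on minus gsr-off (edge ICC)",
            "median_difference": float(np.median(on[ok] - off[ok])),
            "wilcoxon": outcome.to_dict(),
        }
        (outdir / "gsr_comparison.json").write_text(
            json.dumps(comparison, indent=1, sort_keys=True)
        )
        bundle["gsr_comparison"] = comparison

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _versions(),
        "n_regions": len(region_names),
        "n_edges": len(region_names) * (len(region_names) - 1) // 2,
        "subjects_input": n_input,
        "subjects_after_subset": n_subset,
        "subjects_analyzed": len(cohort.subjects),
        "exclusions": exclusions,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True)
    )
    bundle["provenance"] = provenance
    return bundle
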