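"""Per-patient measurement and cohort analysis orchestration.

``run_case`` executes the full measurement chain for one patient —
register post onto pre via stable cranial landmarks (optionally refined by
ICP on the bone surface), reconstruct surfaces from volumes if needed,
build the anatomical frame, cut the regions and measure thickness changes
— and writes one CSV row plus a JSON provenance block sufficient to
re-derive every number (planes, axes, transform, sample counts).

``run_cohort`` reproduces the cohort analysis on a patient table:
per-group descriptives with normality-gated between-group tests, one-sample
tests of the thickness changes against zero, the Spearman correlation
matrix, collinearity diagnostics and standardized multiple regression with
backward elimination, and per-group regression-line data for scatter plots.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh

from .anatomy import LandmarkSet, build_frame, fma, anb
from .regions import TimepointData, patient_changes
from .transforms import RigidTransform, apply_transform, icp_refine, kabsch, load_transform
from . import stats as mstats

logger = logging.getLogger("massetry")

__all__ = ["CaseConfig", "AnalysisConfig", "run_case", "run_cohort", "StageError"]

RESULT_COLUMNS = [
    "patient_id",
    "MAS_change_mm",
    "MM_change_mm",
    "FT_change_mm",
    "ST_pre_mm",
    "FMA_deg",
    "ANB_deg",
]


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class CaseConfig:
    """One patient's inputs and processing options.

    ``pre_dir``/``post_dir`` each hold one modality per structure: either
    ``<name>.stl`` surfaces or ``<name>.npz`` voxel volumes (thresholded
    and isosurfaced using ``thresholds[<name>]``), plus ``landmarks.json``.
    Structures: ``face``, ``masseter_L``, ``masseter_R`` and optionally
    ``skull`` (needed for ICP refinement).
    """

    patient_id: str
    pre_dir: str
    post_dir: str
    output_dir: str = "."
    registration: str = "landmark"  # landmark | landmark+icp | precomputed
    transform_path: Optional[str] = None
    registration_landmark_prefix: str = "skull"
    sides: Sequence[str] = ("L", "R")
    thresholds: Dict[str, float] = field(default_factory=dict)
    icp_tol_mm: float = 1e-4
    icp_max_iter: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


def _load_structure(directory: Path, name: str, thresholds: Dict[str, float]):
    stl = directory / f"{name}.stl"
    npz = directory / f"{name}.npz"
    if stl.exists() and npz.exists():
        raise StageError(
            "load", f"both mesh and volume present for {name!r} in {directory}"
        )
    if stl.exists():
        mesh = trimesh.load(str(stl), force="mesh", process=False)
        if len(mesh.faces) == 0:
            raise StageError("load", f"empty mesh {stl}")
        return mesh
    if npz.exists():
        from .volume import VoxelVolume, extract_isosurface, threshold_segment

        if name not in thresholds:
            raise StageError(
                "segment", f"no threshold configured for volume input {name!r}"
            )
        vol = VoxelVolume.load_npz(npz)
        mask = threshold_segment(vol, thresholds[name])
        return extract_isosurface(mask)
    raise StageError("load", f"no {name}.stl or {name}.npz in {directory}")


def _load_timepoint(directory: Path, config: CaseConfig, need_skull: bool):
    lm_path = directory / "landmarks.json"
    if not lm_path.exists():
        raise StageError("load", f"missing landmark file {lm_path}")
    landmarks = LandmarkSet.from_json(lm_path)
    face = _load_structure(directory, "face", config.thresholds)
    masseters = {
        s: _load_structure(directory, f"masseter_{s}", config.thresholds)
        for s in config.sides
    }
    skull = None
    if need_skull:
        skull = _load_structure(directory, "skull", config.thresholds)
    return TimepointData(face=face, masseters=masseters, landmarks=landmarks), skull


def _registration_points(landmarks: LandmarkSet, prefix: str) -> np.ndarray:
    names = sorted(n for n in landmarks.points if n.startswith(prefix))
    if len(names) < 3:
        raise StageError(
            "register", f"need >= 3 landmarks with prefix {prefix!r}, got {len(names)}"
        )
    return np.array([landmarks[n] for n in names])


def run_case(config: CaseConfig):
    """Measure one patient; returns ``(PatientChanges, row dict)``.

    Writes ``<patient_id>_changes.csv`` and ``<patient_id>_provenance.json``
    to the output directory. Deterministic and idempotent for fixed inputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    need_icp = config.registration == "landmark+icp"

    pre, pre_skull = _load_timepoint(Path(config.pre_dir), config, need_icp)
    post, post_skull = _load_timepoint(Path(config.post_dir), config, need_icp)

    # --- registration on treatment-stable cranial structures only ---
    try:
        if config.registration == "precomputed":
            if not config.transform_path:
                raise ValueError("precomputed registration needs transform_path")
            T = load_transform(config.transform_path)
        else:
            src = _registration_points(post.landmarks, config.registration_landmark_prefix)
            tgt = _registration_points(pre.landmarks, config.registration_landmark_prefix)
            T = kabsch(src, tgt)
            if need_icp:
                res = icp_refine(
                    apply_transform(post_skull, T),
                    pre_skull,
                    tol=config.icp_tol_mm,
                    max_iter=config.icp_max_iter,
                )
                T = res.transform.compose(T)
                if not res.converged:
                    logger.warning("ICP did not converge (RMS %.4f mm)", res.rms)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate with stage
        raise StageError("register", str(e)) from e

    post_aligned = TimepointData(
        face=apply_transform(post.face, T),
        masseters={s: apply_transform(m, T) for s, m in post.masseters.items()},
        landmarks=post.landmarks.transformed(T.apply),
    )

    try:
        frame = build_frame(pre.landmarks)
        fma_deg = fma(frame, pre.landmarks)
        anb_deg = anb(pre.landmarks, frame)
    except Exception as e:  # noqa: BLE001
        raise StageError("frame", str(e)) from e

    try:
        changes, provenance = patient_changes(
            pre, post_aligned, frame=frame, sides=tuple(config.sides)
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("measure", str(e)) from e

    row = {
        "patient_id": config.patient_id,
        "MAS_change_mm": changes.mas_change_mm,
        "MM_change_mm": changes.mm_change_mm,
        "FT_change_mm": changes.ft_change_mm,
        "ST_pre_mm": changes.st_pre_mm,
        "FMA_deg": fma_deg,
        "ANB_deg": anb_deg,
    }
    pd.DataFrame([row], columns=RESULT_COLUMNS).to_csv(
        out_dir / f"{config.patient_id}_changes.csv", index=False
    )
    prov = {
        "patient_id": config.patient_id,
        "registration": {
            "mode": config.registration,
            "matrix": T.matrix().tolist(),
            "rotation_deg": T.angle_deg(),
        },
        "per_side": provenance,
        "per_side_values": changes.per_side,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out_dir / f"{config.patient_id}_provenance.json").write_text(
        json.dumps(prov, indent=2)
    )
    return changes, row


# --------------------------------------------------------------------------
# cohort analysis
# --------------------------------------------------------------------------

DESCRIPTIVE_VARS = ["duration_d", "age_y", "FMA_deg", "ANB_deg", "ST_pre_mm"]
CHANGE_VARS = ["MAS_change_mm", "MM_change_mm", "FT_change_mm"]
PREDICTORS = ["extraction", "ST_pre_mm", "FMA_deg", "ANB_deg", "age_y", "duration_d"]


@dataclass
class AnalysisConfig:
    alpha_norm: float = 0.05
    t_variant: str = "pooled"
    backward_alpha: Optional[float] = 0.05
    group_column: str = "extraction"


def run_cohort(
    table: pd.DataFrame | str,
    config: AnalysisConfig | None = None,
    output_dir: Optional[str] = None,
) -> dict:
    """Cohort statistics on a patient table (DataFrame or CSV path).

    Returns a report dict with descriptives, thickness-change tests,
    Spearman matrix, VIF, regression results and per-group scatter-plot
    slopes; optionally writes them as CSV/JSON files. Row order does not
    affect any output.
    """
    if config is None:
        config = AnalysisConfig()
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    if len(table) < 2:
        raise ValueError("cohort table needs >= 2 rows")
    gcol = config.group_column
    has_groups = gcol in table.columns and table[gcol].nunique() == 2
    if not has_groups:
        logger.warning("single-group table: between-group outputs skipped")

    present = lambda cols: [c for c in cols if c in table.columns]  # noqa: E731

    # descriptives + between-group comparison
    desc_rows = []
    for var in present(DESCRIPTIVE_VARS + CHANGE_VARS):
        row = {"variable": var}
        if has_groups:
            for lab, sub in table.groupby(gcol):
                row[f"mean_{lab}"] = sub[var].mean()
                row[f"sd_{lab}"] = sub[var].std(ddof=1)
            res = mstats.test_router(
                table[var].to_numpy(),
                table[gcol].to_numpy(),
                alpha_norm=config.alpha_norm,
                t_variant=config.t_variant,
            )
            row["between_p"] = res.p_value
            row["between_method"] = res.method
        else:
            row["mean"] = table[var].mean()
            row["sd"] = table[var].std(ddof=1)
        desc_rows.append(row)
    descriptives = pd.DataFrame(desc_rows)

    # thickness changes vs zero, per group
    change_rows = []
    groups = table.groupby(gcol) if has_groups else [("all", table)]
    for var in present(CHANGE_VARS):
        for lab, sub in groups if has_groups else [("all", table)]:
            res = mstats.test_router(
                sub[var].to_numpy(), alpha_norm=config.alpha_norm
            )
            change_rows.append(
                {
                    "variable": var,
                    "group": lab,
                    "n": len(sub),
                    "mean": sub[var].mean(),
                    "sd": sub[var].std(ddof=1),
                    "p_vs_zero": res.p_value,
                    "method": res.method,
                }
            )
    change_tests = pd.DataFrame(change_rows)

    corr_cols = present(
        ["duration_d", "age_y", "FMA_deg", "ANB_deg",
         "MM_change_mm", "MAS_change_mm", "FT_change_mm", "ST_pre_mm"]
    )
    rho, rho_p, corr_flags = mstats.spearman_matrix(table, corr_cols)

    # constant columns carry no information and break standardization
    predictors = [c for c in present(PREDICTORS) if table[c].nunique() > 1]
    dropped = [c for c in present(PREDICTORS) if c not in predictors]
    if dropped:
        logger.warning("constant predictors dropped from regression: %s", dropped)
    vifs = mstats.vif(table, predictors) if len(predictors) >= 2 else {}
    regressions = {}
    for resp in present(CHANGE_VARS):
        if table[resp].nunique() < 2 or not predictors:
            logger.warning("regression skipped for %s", resp)
            continue
        try:
            regressions[resp] = {
                "selected": mstats.ols_standardized(
                    table, resp, predictors, backward_alpha=config.backward_alpha
                ),
                "full": mstats.ols_standardized(table, resp, predictors),
            }
        except ValueError as e:  # singular design on degenerate tables
            logger.warning("regression failed for %s: %s", resp, e)

    # per-group regression-line data (MM and FT change against MAS change)
    scatter_rows = []
    if has_groups and "MAS_change_mm" in table.columns:
        import statsmodels.api as sm

        for yvar in present(["MM_change_mm", "FT_change_mm"]):
            for lab, sub in table.groupby(gcol):
                if sub["MAS_change_mm"].nunique() < 2:
                    continue  # no regression line on a degenerate abscissa
                X = sm.add_constant(sub["MAS_change_mm"].to_numpy(dtype=float))
                fit = sm.OLS(sub[yvar].to_numpy(dtype=float), X).fit()
                scatter_rows.append(
                    {
                        "y": yvar,
                        "x": "MAS_change_mm",
                        "group": lab,
                        "slope": fit.params[1],
                        "intercept": fit.params[0],
                        "r2": fit.rsquared,
                    }
                )
    scatter = pd.DataFrame(scatter_rows)

    report = {
        "n": len(table),
        "descriptives": descriptives,
        "change_tests": change_tests,
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "spearman_flags": corr_flags,
        "vif": vifs,
        "regressions": regressions,
        "scatter": scatter,
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        descriptives.to_csv(out / "descriptives.csv", index=False)
        change_tests.to_csv(out / "change_tests.csv", index=False)
        rho.to_csv(out / "spearman_rho.csv")
        rho_p.to_csv(out / "spearman_p.csv")
        scatter.to_csv(out / "scatter_slopes.csv", index=False)
        reg_json = {
            resp: {
                kind: dataclasses.asdict(r)
                for kind, r in fits.items()
            }
            for resp, fits in regressions.items()
        }
        (out / "stats_report.json").write_text(
            json.dumps(
                {"n": len(table), "vif": vifs, "regressions": reg_json,
                 "spearman_flags": corr_flags},
                indent=2,
            )
        )
    return report
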