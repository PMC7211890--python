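"""Interaction surfaces and conditional-effect lines for the fitted model.

Predicted bill surface area is shown over a lattice of one relative
temperature extremity axis crossed with a moderator (mean temperature
or recent precipitation), with every other covariate held at its sample
mean, factors at their reference levels, the spatial smooth evaluated
at the data centroid and random effects at zero.  Grid regions outside
the kernel-density support of the observed (RTE, moderator) points are
masked, mirroring the convention of shading out the area beyond the
density region containing 99.9% of datapoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .gamm import FitResult, predict_with_ci, r2_nakagawa, wald_tests

__all__ = [
    "SurfaceGrid",
    "interaction_surface",
    "kde_mask",
    "conditional_effect",
    "render_report",
]

RTE_COLUMNS = {"min": "rel_min_temp", "max": "rel_max_temp"}
MODERATORS = ("mean_temp", "recent_precip")


@dataclass
class SurfaceGrid:
    rte: str
    moderator: str
    axis1: np.ndarray  # RTE values
    axis2: np.ndarray  # moderator values
    predicted: np.ndarray  # (grid_n, grid_n), axis1 varies along rows
    mask: np.ndarray  # True where inside the density support


def _baseline_row(fit: FitResult) -> dict:
    """Covariate point: numeric covariates at sample means, factors at
    reference levels (subspecies pinosus, sex female)."""
    frame = fit.designs.frame
    body = fit.designs.spec.bodysize_column
    row = {
        nm: float(frame[nm].mean())
        for nm in ("rel_min_temp", "rel_max_temp", "mean_temp", "temp_sd", "recent_precip")
    }
    row["month"] = float(frame["month"].mean())
    row[body] = float(frame[body].mean())
    row["subspecies_thurberi"] = 0.0
    row["sex_male"] = 0.0
    return row


def kde_mask(points: np.ndarray, grid_x: np.ndarray, grid_y: np.ndarray, level: float = 0.999):
    """Boolean mask of grid cells inside the KDE region holding `level`
    of the data points.

    A 2D Gaussian KDE (Scott bandwidth) is evaluated at the data points;
    the density threshold is the (1−level) quantile of those values, so
    the retained region contains the requested fraction of points.
    Returns a (len(grid_x), len(grid_y)) mask (x varies along rows).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 points for a density mask")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError("degenerate points: no spread on one axis")
    try:
        kde = stats.gaussian_kde(pts.T, bw_method="scott")
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate (collinear) points") from exc
    dens_at_points = kde(pts.T)
    thresh = np.quantile(dens_at_points, 1.0 - level)
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return dens >= thresh


def kde_retained_fraction(points: np.ndarray, level: float = 0.999) -> float:
    """Fraction of the data points whose own KDE density meets the mask
    threshold — the point-wise counterpart of :func:`kde_mask` (free of
    grid discretization)."""
    pts = np.asarray(points, dtype=float)
    kde = stats.gaussian_kde(pts.T, bw_method="scott")
    dens = kde(pts.T)
    thresh = np.quantile(dens, 1.0 - level)
    return float(np.mean(dens >= thresh))


def interaction_surface(
    fit: FitResult,
    rte: str = "min",
    moderator: str = "mean_temp",
    grid_n: int = 100,
    density_level: float = 0.999,
) -> SurfaceGrid:
    """Predicted SA over an RTE × moderator lattice spanning the observed
    ranges (all other covariates at sample means, smooth at centroid)."""
    if moderator not in MODERATORS:
        raise ValueError(f"moderator must be one of {MODERATORS}")
    rte_col = RTE_COLUMNS[rte]
    frame = fit.designs.frame
    x1 = np.linspace(frame[rte_col].min(), frame[rte_col].max(), grid_n)
    x2 = np.linspace(frame[moderator].min(), frame[moderator].max(), grid_n)
    base = _baseline_row(fit)
    rows = []
    for a in x1:
        for b in x2:
            r = dict(base)
            r[rte_col] = float(a)
            r[moderator] = float(b)
            rows.append(r)
    preds = predict_with_ci(fit, pd.DataFrame(rows))
    predicted = preds["fit"].to_numpy().reshape(grid_n, grid_n)
    pts = frame[[rte_col, moderator]].to_numpy()
    mask = kde_mask(pts, x1, x2, level=density_level)
    return SurfaceGrid(rte=rte, moderator=moderator, axis1=x1, axis2=x2,
                       predicted=predicted, mask=mask)


def conditional_effect(
    fit: FitResult,
    rte: str = "min",
    moderator: str = "mean_temp",
    percentiles: tuple[float, float] = (10.0, 90.0),
    n_points: int = 100,
    level: float = 0.95,
) -> dict:
    """SA vs. RTE at the moderator fixed at its sample percentiles
    (linear-interpolation convention), with pointwise CIs from the
    coefficient covariance (delta method on the linear predictor)."""
    rte_col = RTE_COLUMNS[rte]
    frame = fit.designs.frame
    x = np.linspace(frame[rte_col].min(), frame[rte_col].max(), n_points)
    base = _baseline_row(fit)
    out = {"rte": rte, "moderator": moderator, "x": x, "lines": {}}
    for pc in percentiles:
        mval = float(np.percentile(frame[moderator], pc))
        rows = []
        for a in x:
            r = dict(base)
            r[rte_col] = float(a)
            r[moderator] = mval
            rows.append(r)
        preds = predict_with_ci(fit, pd.DataFrame(rows), level=level)
        out["lines"][pc] = {
            "moderator_value": mval,
            "fit": preds["fit"].to_numpy(),
            "lo": preds["lo"].to_numpy(),
            "hi": preds["hi"].to_numpy(),
        }
    return out


def _plot_surface(sg: SurfaceGrid, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    shown = np.where(sg.mask, sg.predicted, np.nan)
    pcm = ax.pcolormesh(sg.axis1, sg.axis2, shown.T, shading="auto", cmap="plasma")
    ax.set_facecolor("0.8")
    fig.colorbar(pcm, ax=ax, label="predicted bill surface area (mm²)")
    ax.set_xlabel(f"relative {sg.rte} temp")
    ax.set_ylabel(sg.moderator)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_lines(lines: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for pc, ln in lines["lines"].items():
        ax.fill_between(lines["x"], ln["lo"], ln["hi"], alpha=0.3)
        ax.plot(lines["x"], ln["fit"], label=f"{lines['moderator']} p{pc:g} = {ln['moderator_value']:.1f}")
    ax.set_xlabel(f"relative {lines['rte']} temp")
    ax.set_ylabel("predicted bill surface area (mm²)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    fit: FitResult,
    surfaces: list[SurfaceGrid],
    lines: list[dict],
    path,
    n_rejected: int = 0,
) -> dict[str, str]:
    """Write figures, the coefficient CSV, a model JSON and a Markdown
    summary.  Deterministic given identical inputs."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for sg in surfaces:
        f = out / f"surface_rel_{sg.rte}_x_{sg.moderator}.png"
        _plot_surface(sg, f)
        files[f.stem] = str(f)
    for ln in lines:
        f = out / f"conditional_rel_{ln['rte']}_x_{ln['moderator']}.png"
        _plot_lines(ln, f)
        files[f.stem] = str(f)

    coefs = wald_tests(fit)
    coef_path = out / "coefficients.csv"
    coefs.to_csv(coef_path, index=False, float_format="%.6g")
    files["coefficients"] = str(coef_path)

    r2m, r2c = r2_nakagawa(fit)
    model = {
        "n": int(len(fit.y)),
        "n_rejected": int(n_rejected),
        "edf_smooth": fit.edf_smooth,
        "sigma2_year": fit.sigma2_year,
        "sd_year": fit.sd_year,
        "sigma2_resid": fit.sigma2_resid,
        "sd_resid": fit.sd_resid,
        "marginal_r2": r2m,
        "conditional_r2": r2c,
        "reml_criterion": fit.reml_criterion,
        "converged": bool(fit.converged),
        "boundary": fit.boundary,
        "coefficients": {
            row["term"]: {"estimate": None if pd.isna(row["estimate"]) else row["estimate"],
                          "se": None if pd.isna(row["se"]) else row["se"],
                          "statistic": row["statistic"], "p": row["p"]}
            for _, row in coefs.iterrows()
        },
    }
    model_path = out / "model.json"
    with open(model_path, "w") as fh:
        json.dump(model, fh, indent=2, sort_keys=True)
    files["model"] = str(model_path)

    md = [
        "# Model report",
        "",
        f"- specimens used: {len(fit.y)}",
        f"- specimens rejected: {n_rejected}",
        f"- smooth edf: {fit.edf_smooth:.2f}",
        f"- year variance ± sd: {fit.sigma2_year:.3f} ± {fit.sd_year:.3f}",
        f"- residual variance ± sd: {fit.sigma2_resid:.3f} ± {fit.sd_resid:.3f}",
        f"- marginal R²: {r2m:.3f}; conditional R²: {r2c:.3f}",
        "",
        "```",
        coefs.to_string(index=False),
        "```",
        "",
    ]
    md_path = out / "report.md"
    md_path.write_text("\n".join(md))
    files["report"] = str(md_path)
    return files
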