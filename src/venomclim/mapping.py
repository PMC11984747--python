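"""Pixel-wise projection of fitted activity models onto bioclim rasters.

A fitted (possibly response-transformed) linear model is evaluated at
every pixel of an aligned bioclim covariate stack, back-transformed to
activity units, and packaged with marginal per-row/per-column mean
profiles and an extrapolation mask (pixels whose covariates fall outside
the training range).  NoData in any covariate propagates to NoData in
the prediction.  The GeoTIFF is the contract artifact; the rendered
blue-to-red PNG is a convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geo import RasterGrid, write_raster, read_raster
from .regression import FitResult, back_transform


class MissingCovariateError(KeyError):
    """The raster stack lacks a predictor required by the model."""


@dataclass
class PredictionMap:
    """Predicted activity surface in response units."""

    grid: RasterGrid
    model_id: str
    summary: dict
    row_profile: np.ndarray       # per-row mean over valid pixels
    col_profile: np.ndarray       # per-column mean over valid pixels
    extrapolation_mask: RasterGrid | None = None
    flags: list[str] = field(default_factory=list)


def _stack_dict(stack) -> dict[str, RasterGrid]:
    if isinstance(stack, dict):
        return stack
    return {g.band_name: g for g in stack}


def predict_surface(
    fit: FitResult,
    stack,
    *,
    training_ranges: dict[str, tuple[float, float]] | None = None,
) -> PredictionMap:
    """Evaluate ``fit`` at every pixel of an aligned covariate stack.

    ``stack`` is a dict (or list, keyed by ``band_name``) of
    :class:`RasterGrid` holding one layer per model predictor.  Layer
    order is irrelevant; the model's predictor names select the layers.
    ``training_ranges`` (per-predictor (min, max) seen at fit time)
    enables the extrapolation mask.
    """
    grids = _stack_dict(stack)
    missing = [p for p in fit.predictors if p not in grids]
    if missing:
        raise MissingCovariateError(
            f"raster stack lacks covariate layers {missing}"
        )
    layers = [grids[p] for p in fit.predictors]
    ref = layers[0]
    for name, g in zip(fit.predictors[1:], layers[1:]):
        if not g.aligned_with(ref):
            raise ValueError(f"covariate layer {name!r} is not aligned with the stack")

    lin = np.full(ref.shape, float(fit.intercept), dtype=float)
    valid = np.ones(ref.shape, dtype=bool)
    extrap = np.zeros(ref.shape, dtype=bool)
    for name, g in zip(fit.predictors, layers):
        vals = np.asarray(g.values, dtype=float)
        ok = np.isfinite(vals)
        valid &= ok
        lin += np.where(ok, fit.coef[name] * vals, 0.0)
        if training_ranges and name in training_ranges:
            lo, hi = training_ranges[name]
            extrap |= ok & ((vals < lo) | (vals > hi))

    with np.errstate(over="ignore", invalid="ignore"):
        pred = back_transform(lin, fit.transform)
    pred = np.asarray(pred, dtype=float)
    pred[~valid] = np.nan
    flags = []
    n_bad = int(np.sum(valid & ~np.isfinite(pred)))
    if n_bad:
        flags.append(f"{n_bad} pixels undefined after back-transform")
    pred[~np.isfinite(pred)] = np.nan

    finite = np.isfinite(pred)
    if finite.any():
        summary = {
            "min": float(np.nanmin(pred)),
            "max": float(np.nanmax(pred)),
            "mean": float(np.nanmean(pred)),
            "n_valid": int(finite.sum()),
            "n_total": int(pred.size),
        }
    else:
        summary = {
            "min": None, "max": None, "mean": None,
            "n_valid": 0, "n_total": int(pred.size),
        }
        flags.append("empty_domain")

    filled = np.where(finite, pred, 0.0)
    with np.errstate(invalid="ignore"):
        row_n, col_n = finite.sum(axis=1), finite.sum(axis=0)
        row_profile = np.where(row_n > 0, filled.sum(axis=1) / np.maximum(row_n, 1), np.nan)
        col_profile = np.where(col_n > 0, filled.sum(axis=0) / np.maximum(col_n, 1), np.nan)

    out_grid = RasterGrid(
        values=pred,
        transform=ref.transform,
        crs=ref.crs,
        band_name=f"{fit.response}_predicted",
        nodata=ref.nodata,
    )
    extrap_grid = None
    if training_ranges:
        em = extrap.astype(np.float32)
        em[~valid] = np.nan
        extrap_grid = RasterGrid(
            values=em,
            transform=ref.transform,
            crs=ref.crs,
            band_name=f"{fit.response}_extrapolation_mask",
            nodata=ref.nodata,
        )
    return PredictionMap(
        grid=out_grid,
        model_id=f"{fit.response}:{fit.transform}:{'+'.join(fit.predictors)}",
        summary=summary,
        row_profile=row_profile,
        col_profile=col_profile,
        extrapolation_mask=extrap_grid,
        flags=flags,
    )


def export_prediction(
    pmap: PredictionMap, path, *, render_png: bool = False
) -> dict[str, Path]:
    """Write the GeoTIFF, a JSON summary sidecar, and optionally a PNG.

    ``path`` is the GeoTIFF path; the sidecar takes the ``.json`` suffix
    and the optional rendering (blue-to-red gradient with marginal
    activity strips) the ``.png`` suffix.
    """
    path = Path(path)
    written: dict[str, Path] = {}
    written["geotiff"] = write_raster(pmap.grid, path)
    if pmap.extrapolation_mask is not None:
        mask_path = path.with_name(path.stem + "_extrapolation" + path.suffix)
        written["extrapolation_mask"] = write_raster(pmap.extrapolation_mask, mask_path)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "model_id": pmap.model_id,
                "summary": pmap.summary,
                "flags": pmap.flags,
                "row_profile": [
                    None if not np.isfinite(v) else float(v) for v in pmap.row_profile
                ],
                "col_profile": [
                    None if not np.isfinite(v) else float(v) for v in pmap.col_profile
                ],
            },
            fh,
            indent=2,
        )
    written["summary"] = sidecar
    if render_png:
        written["png"] = _render_png(pmap, path.with_suffix(".png"))
    return written


def _render_png(pmap: PredictionMap, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import gridspec

    vals = pmap.grid.values
    fig = plt.figure(figsize=(7, 7))
    gs = gridspec.GridSpec(
        2, 2, width_ratios=[5, 1], height_ratios=[1, 5], hspace=0.05, wspace=0.05
    )
    ax_top = fig.add_subplot(gs[0, 0])
    ax_map = fig.add_subplot(gs[1, 0])
    ax_right = fig.add_subplot(gs[1, 1])
    ext = pmap.grid.extent
    im = ax_map.imshow(
        vals,
        cmap="coolwarm",
        extent=[ext.lon_min, ext.lon_max, ext.lat_min, ext.lat_max],
        aspect="auto",
    )
    ax_map.set_xlabel("longitude")
    ax_map.set_ylabel("latitude")
    cols = np.linspace(ext.lon_min, ext.lon_max, len(pmap.col_profile))
    rows = np.linspace(ext.lat_max, ext.lat_min, len(pmap.row_profile))
    ax_top.plot(cols, pmap.col_profile, color="grey")
    ax_top.set_xlim(ext.lon_min, ext.lon_max)
    ax_top.set_xticks([])
    ax_right.plot(pmap.row_profile, rows, color="grey")
    ax_right.set_ylim(ext.lat_min, ext.lat_max)
    ax_right.set_yticks([])
    fig.colorbar(im, ax=ax_map, orientation="horizontal", pad=0.12, label=pmap.model_id)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def load_prediction(path) -> RasterGrid:
    """Re-read an exported prediction GeoTIFF."""
    return read_raster(path)
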