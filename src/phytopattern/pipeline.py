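"""End-to-end workflows and their reports.

Two workflows mirror the two halves of the study: ``analyze_image``
runs the detection and statistics chain on a patch raster;
``simulate_and_analyze`` renders a synthetic scene, integrates the
phytomass equation, and runs the same statistics on the simulated
field, so field observations and model output can be compared like for
like.  Both return an :class:`AnalysisReport` whose provenance block
(config, seeds, input hash) is sufficient to re-run them bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .detection import DEFAULT_MIN_DIAMETER_M, binarize, label_patches, preprocess
from .dynamics import RunConfig, ScalarField, integrate, patch_threshold
from .model import ModelParams
from .scenes import SceneSpec, render_scene
from .stats import (
    fit_inverse_gaussian,
    fit_rayleigh,
    nnd_boundary,
    radial_spectrum,
    voronoi_summary,
)

__all__ = ["AnalysisReport", "analyze_image", "simulate_and_analyze"]


@dataclasses.dataclass
class AnalysisReport:
    """Machine-readable summary of one workflow run."""

    provenance: dict
    n_patches: int
    area_mean: float
    area_sd: float
    r_eq_mean: float
    r_eq_sd: float
    nnd_n_valid: int
    nnd_mean: float
    nnd_sd: float
    k_max: Optional[float]
    characteristic_length: Optional[float]
    voronoi_modal_vertices: Optional[int]
    voronoi_fraction_six: Optional[float]
    voronoi_mean_area: Optional[float]
    voronoi_equivalent_radius: Optional[float]
    rayleigh_sigma: Optional[float]
    invgauss_mu: Optional[float]
    invgauss_lambda: Optional[float]
    extra: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        from .io import write_json

        write_json(path, self.to_dict())


def _summarize(
    patches, *, pixel_size: float, provenance: dict, extra: Optional[dict] = None,
    spectrum_input: Optional[np.ndarray] = None,
) -> AnalysisReport:
    """Shared statistics block for both workflows (units follow pixel_size)."""
    table = patches.table
    if len(table) == 0:
        raise ValueError("no patches detected; nothing to summarise")
    nnd = nnd_boundary(patches)
    valid = nnd[nnd["valid"]]
    spec = (
        radial_spectrum(spectrum_input, pixel_size)
        if spectrum_input is not None
        else None
    )
    vor = None
    if len(table) >= 4:
        centers = table[["row", "col"]].to_numpy() * pixel_size
        try:
            vor = voronoi_summary(
                centers,
                (0.0, patches.shape[0] * pixel_size, 0.0, patches.shape[1] * pixel_size),
            )
        except ValueError:
            vor = None
    ray = fit_rayleigh(valid["nnd_m"]) if len(valid) >= 2 else None
    ig = None
    if vor is not None and len(vor.cells) >= 2:
        try:
            ig = fit_inverse_gaussian(vor.cells["area"])
        except ValueError:
            ig = None
    return AnalysisReport(
        provenance=provenance,
        n_patches=len(table),
        area_mean=float(table["area_m2"].mean()),
        area_sd=float(table["area_m2"].std(ddof=1)) if len(table) > 1 else 0.0,
        r_eq_mean=float(table["r_eq_m"].mean()),
        r_eq_sd=float(table["r_eq_m"].std(ddof=1)) if len(table) > 1 else 0.0,
        nnd_n_valid=int(len(valid)),
        nnd_mean=float(valid["nnd_m"].mean()) if len(valid) else float("nan"),
        nnd_sd=float(valid["nnd_m"].std(ddof=1)) if len(valid) > 1 else float("nan"),
        k_max=None if spec is None else spec.k_max,
        characteristic_length=None if spec is None else spec.characteristic_length,
        voronoi_modal_vertices=None if vor is None else vor.modal_vertex_count,
        voronoi_fraction_six=None if vor is None else vor.fraction_six_sided,
        voronoi_mean_area=None if vor is None else vor.mean_area,
        voronoi_equivalent_radius=None if vor is None else vor.equivalent_radius,
        rayleigh_sigma=None if ray is None else ray.params["sigma"],
        invgauss_mu=None if ig is None else ig.params["mu"],
        invgauss_lambda=None if ig is None else ig.params["lambda"],
        extra=extra or {},
    )


def analyze_image(
    image: Union[np.ndarray, str, Path],
    pixel_size: float,
    *,
    median_size: int = 3,
    method: str = "otsu",
    threshold: Optional[float] = None,
    polarity: str = "dark",
    min_diameter_m: float = DEFAULT_MIN_DIAMETER_M,
    out_dir: Optional[Path] = None,
) -> AnalysisReport:
    """Detection and statistics chain on a patch raster.

    All lengths in the report are metres (``pixel_size`` metres per
    pixel).  The Fourier spectrum is computed on the binary patch mask.
    With ``out_dir`` set, the patch table, NND table and report JSON
    are written there.
    """
    if isinstance(image, (str, Path)):
        from .io import read_image

        path = Path(image)
        image = read_image(path)
        source = str(path)
    else:
        source = "<array>"
    image = np.asarray(image)
    digest = hashlib.sha256(np.ascontiguousarray(image).tobytes()).hexdigest()[:16]
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    enhanced = preprocess(image, median_size=median_size)
    mask = binarize(enhanced, method=method, threshold=threshold, polarity=polarity)
    patches = label_patches(mask, pixel_size, min_diameter_m=min_diameter_m)
    if len(patches) == 0:
        raise ValueError("no patches detected in the image")
    provenance = {
        "workflow": "analyze_image",
        "version": __version__,
        "source": source,
        "input_sha256_16": digest,
        "pixel_size": pixel_size,
        "median_size": median_size,
        "method": method,
        "threshold": threshold,
        "polarity": polarity,
        "min_diameter_m": min_diameter_m,
    }
    report = _summarize(
        patches,
        pixel_size=pixel_size,
        provenance=provenance,
        spectrum_input=mask.astype(float),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        patches.to_csv(out_dir / "patches.csv")
        nnd_boundary(patches).to_csv(out_dir / "nnd.csv", index=False)
        report.write(out_dir / "report.json")
    return report


def simulate_and_analyze(
    scene: SceneSpec,
    params: ModelParams,
    cfg: RunConfig,
    *,
    out_dir: Optional[Path] = None,
) -> AnalysisReport:
    """Render a scene, integrate the phytomass equation, analyse the result.

    The final field is thresholded at half the reference patch plateau
    and fed through the same statistics as an image, with one pixel as
    the length unit (the simulation's natural arbitrary unit; the
    dx-scaled equivalents are in ``extra``).  Patch structures are kept
    regardless of size, and there is no border removal beyond the NND
    validity rule, since the domain is periodic.
    """
    field, gt = render_scene(scene, mode="field")
    final = integrate(field, params, cfg)[-1][1]
    thr = patch_threshold(params, field.dx)
    mask = final.values > thr
    # periodic domain: border structures are real, keep them
    patches_all = label_patches_keep_border(mask)
    provenance = {
        "workflow": "simulate_and_analyze",
        "version": __version__,
        "scene": dataclasses.asdict(scene),
        "params": dataclasses.asdict(params),
        "run": dataclasses.asdict(cfg),
        "patch_threshold": thr,
    }
    report = _summarize(
        patches_all,
        pixel_size=1.0,
        provenance=provenance,
        spectrum_input=mask.astype(float),
    )
    report.extra = {
        "n_initial_patches": int(len(gt)),
        "dx": field.dx,
        "nnd_mean_dx_units": report.nnd_mean * field.dx,
        "nnd_sd_dx_units": report.nnd_sd * field.dx,
        "final_min": float(final.values.min()),
        "final_max": float(final.values.max()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_field

        write_field(out_dir / "final_field.tiff", final, t=cfg.dt * cfg.n_steps, params=params)
        patches_all.to_csv(out_dir / "patches.csv")
        report.write(out_dir / "report.json")
    return report


def label_patches_keep_border(mask: np.ndarray):
    """Label all 8-connected structures, border-touching included.

    Used for simulated periodic fields, where a structure at the edge
    is genuine; sizes are in pixels (``pixel_size = 1``).
    """
    from skimage import measure

    from .detection import PatchSet

    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        area = float(region.area)
        rows.append(
            {
                "label": region.label,
                "row": cy,
                "col": cx,
                "area_px": int(region.area),
                "area_m2": area,
                "r_eq_m": float(np.sqrt(area / np.pi)),
                "border_touching": False,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "row", "col", "area_px", "area_m2", "r_eq_m", "border_touching"],
    )
    return PatchSet(table=table, label_image=labels, pixel_size=1.0, shape=mask.shape)
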