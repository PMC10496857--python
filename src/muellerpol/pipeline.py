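"""End-to-end orchestration: image in, filtered image + property bands +
summary/quiver/comparison CSVs + machine-readable run log out."""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .cloude import cloude_filter
from .core import ContractError, MaskReason, MuellerImage
from .io import normalize_image, read_mueller_image, write_maps, write_mueller_image
from .maps import (
    azimuth_summary,
    boxwhisker_summary,
    compare_methods,
    decompose_image,
    quiver_export,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; echoed verbatim into the run log."""

    method: str = "both"
    noise_floor_deg: float = 3.0
    cloude_tol: float = 1e-6
    quiver_step_px: int = 20
    substrate_ref_path: str | None = None
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.method not in ("differential", "lu_chipman", "both"):
            raise ContractError(f"unknown method {self.method!r}")
        if self.noise_floor_deg < 0 or self.cloude_tol <= 0:
            raise ContractError("tolerances must be positive")
        if self.quiver_step_px < 1:
            raise ContractError("quiver_step_px must be >= 1")


_SUMMARY_MAPS = ("Rt_deg", "alpha_t")


def run_pipeline(config: RunConfig, input_path: str) -> int:
    """Run filter + decomposition + statistics on one Mueller image.

    Writes, under ``config.output_dir``: the Cloude-filtered image
    (``filtered.tiff``), per-method property bands + summary CSV
    (``<method>_maps.tiff`` / ``<method>_maps_summary.csv``), quiver CSVs,
    a method-comparison CSV when both methods run, and ``run_log.json``
    echoing the configuration and per-stage pixel failure counts.
    Returns 0 on success; fatal errors raise (the CLI maps them to a
    nonzero exit status).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    img = read_mueller_image(input_path)

    substrate_ref = None
    if config.substrate_ref_path:
        ref_img = read_mueller_image(config.substrate_ref_path)
        substrate_ref = ref_img.pixels.reshape(-1, 4, 4).mean(axis=0)

    dec = decompose_image(
        img,
        method=config.method,
        substrate_ref=substrate_ref,
        cloude_tol=config.cloude_tol,
        noise_floor_deg=config.noise_floor_deg,
    )

    normed, _ = normalize_image(img.pixels)
    filtered_pixels, min_eig = cloude_filter(normed, tol=config.cloude_tol)
    write_mueller_image(
        MuellerImage(filtered_pixels, img.wavelength_nm, img.pixel_size_um,
                     (img.provenance + " [cloude-filtered]").strip()),
        os.path.join(config.output_dir, "filtered.tiff"),
    )

    for name, grids in (("differential", dec.differential), ("lu_chipman", dec.lu_chipman)):
        if grids is None:
            continue
        band_maps = {k: v for k, v in grids.items() if v.ndim == 2}
        summaries = [
            boxwhisker_summary(grids[k], dec.mask, map_name=k) for k in _SUMMARY_MAPS
        ]
        summaries.append(
            azimuth_summary(grids["theta_deg"], grids["Rt_deg"], dec.mask,
                            floor_deg=config.noise_floor_deg)
        )
        write_maps(band_maps, dec.mask, os.path.join(config.output_dir, f"{name}_maps.tiff"),
                   summaries=summaries)
        quiver = quiver_export(grids["theta_deg"], grids["Rt_deg"], dec.mask,
                               grid_step_px=config.quiver_step_px)
        quiver.to_frame().to_csv(
            os.path.join(config.output_dir, f"{name}_quiver.csv"), index=False
        )

    if dec.differential is not None and dec.lu_chipman is not None:
        _, comparison = compare_methods(dec.differential, dec.lu_chipman, dec.mask)
        comparison.to_csv(os.path.join(config.output_dir, "method_comparison.csv"),
                          index=False)

    reasons = dec.mask.reason
    log = {
        "muellerpol_version": __version__,
        "input": str(input_path),
        "config": asdict(config),
        "image_shape": list(img.shape),
        "n_pixels": int(np.prod(img.shape)),
        "n_valid": dec.mask.n_valid(),
        "failure_counts": {
            r.name.lower(): int((reasons == r).sum())
            for r in (MaskReason.NON_PHYSICAL, MaskReason.DECOMPOSITION_FAILED,
                      MaskReason.BELOW_NOISE_FLOOR)
        },
        "min_coherency_eigenvalue": float(np.min(min_eig)),
    }
    with open(os.path.join(config.output_dir, "run_log.json"), "w") as f:
        json.dump(log, f, indent=2)
    return 0
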