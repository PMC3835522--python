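"""Image and result I/O.

Grayscale PNG/TIFF (8/16-bit or float) via imageio/tifffile; optional
single-slice NIfTI via nibabel.  Results are written as an indexed PNG
label map, 32-bit float TIFFs for the bias and corrected images, a CSV
energy trace and a plain-text run summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


def read_image(path) -> np.ndarray:
    """Read a single-channel 2-D image as float64.

    RGB(A) inputs are reduced to luminance by channel averaging; NIfTI
    files must contain (or squeeze to) a single 2-D slice.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.squeeze(np.asanyarray(nib.load(str(path)).dataobj))
        if data.ndim != 2:
            raise ValueError(f"expected a single 2-D slice in {path}, got shape {data.shape}")
        return np.asarray(data, dtype=float)
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a 2-D grayscale image")
    return img


def save_results(results, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(outdir / "labels.png", results.labels.astype(np.uint8))
    tifffile.imwrite(outdir / "bias.tif", results.bias.astype(np.float32))
    tifffile.imwrite(
        outdir / "corrected.tif", results.corrected_image.astype(np.float32)
    )
    results.energy_trace.to_csv(outdir / "energy_trace.csv", index=False)
    (outdir / "summary.txt").write_text(results.summary())
    rm = results.region_model
    state = {
        "n_phases": results.model.n_phases,
        "iterations": results.n_iter,
        "converged": results.converged,
        "constants_log": rm.constants.tolist(),
        "constants_intensity": np.exp(rm.constants).tolist(),
        "stddevs_log": rm.stddevs.tolist(),
    }
    (outdir / "state.json").write_text(json.dumps(state, indent=2) + "\n")


def save_phantom(bundle, outdir) -> None:
    """Write a phantom bundle: observed image, labels, bias, sidecar spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "observed.tif", bundle.observed.astype(np.float32))
    iio.imwrite(outdir / "labels.png", bundle.labels.astype(np.uint8))
    tifffile.imwrite(outdir / "bias.tif", bundle.bias.astype(np.float32))
    spec = bundle.spec
    sidecar = {
        "shape": list(spec.shape),
        "shapes": [list(s) for s in spec.shapes],
        "constants": list(spec.constants),
        "bias": repr(spec.bias),
        "noise_sd": np.asarray(spec.noise_sd).tolist(),
        "formation_model": spec.formation_model,
        "seed": spec.seed,
    }
    (outdir / "spec.json").write_text(json.dumps(sidecar, indent=2) + "\n")
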