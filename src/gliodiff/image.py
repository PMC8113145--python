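"""Optional image mode: hotspot rCBV from a 4D NIfTI DSC series plus mask volumes.

The 4D series is (x, y, z, t) in scanner units; tumor and contralateral
masks are NIfTI volumes of identical spatial shape, interpreted as boolean
in index space (affines are read but not used for resampling).  The
reference curve is the mean dR2* over the contralateral normal-appearing
voxels; each masked voxel is leakage-corrected against it and integrated to
a CBV value, and the hotspot ratio is formed exactly as in ROI mode.
"""

from __future__ import annotations

import numpy as np

from .dsc import (CbvResult, DeltaR2Series, DscAcquisition, DscSeries, bw_fit,
                  cbv_integrate, delta_r2star, hotspot_rcbv, reference_curve)

__all__ = ["image_rcbv"]


def _load(path):
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def image_rcbv(series_path, tumor_mask_path, contra_mask_path,
               acquisition: DscAcquisition, k: int = 10,
               integration_window: tuple[int, int] | None = None) -> CbvResult:
    """Leakage-corrected hotspot rCBV_max from NIfTI inputs.

    ``integration_window`` defaults to every frame after the baseline
    window.  Returns the same CbvResult as the ROI pathway.
    """
    data = _load(series_path)
    if data.ndim != 4:
        raise ValueError(f"series must be 4D (x, y, z, t); got shape {data.shape}")
    if data.shape[-1] != acquisition.n_frames:
        raise ValueError("series frame count does not match the acquisition")
    tumor = _load(tumor_mask_path).astype(bool)
    contra = _load(contra_mask_path).astype(bool)
    if tumor.shape != data.shape[:3] or contra.shape != data.shape[:3]:
        raise ValueError("mask shapes must match the series spatial shape")

    times = acquisition.times
    if integration_window is None:
        integration_window = (acquisition.baseline_window[1], acquisition.n_frames)

    def voxel_dr2(mask):
        sig = data[mask].T  # (t, n_voxels)
        return delta_r2star(DscSeries(times=times, signal=sig, acquisition=acquisition))

    contra_dr2 = voxel_dr2(contra)
    ref = reference_curve([DeltaR2Series(times, v) for v in contra_dr2.values.T])

    shape = data.shape[:3]
    cbv = np.zeros(shape)
    for mask in (tumor, contra):
        dr2 = voxel_dr2(mask)
        vals = np.empty(dr2.values.shape[1])
        for i in range(vals.size):
            fit = bw_fit(DeltaR2Series(times, dr2.values[:, i]), ref)
            vals[i] = cbv_integrate(fit.corrected, integration_window)
        cbv[mask] = vals
    return hotspot_rcbv(cbv.ravel(), tumor.ravel(), contra.ravel(), k=k)
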