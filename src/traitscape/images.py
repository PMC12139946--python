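"""Map containers, masking, scaling and multivariate outlier exclusion.

The pipeline currency is :class:`BrainMaps`: a dense observations x voxels
matrix of contrast or trial maps on a 3-D voxel grid, together with the grid
coordinates of each column, a gray-matter mask, per-row observation metadata
and a provenance trail of the transforms applied.

Two normalisations recur throughout and must not be confused:

* **image-wise scaling** operates on rows: centering subtracts each
  observation's own mean across voxels (removing any per-person global
  activity offset exactly), z-scoring additionally divides by the row SD;
* **voxel-wise standardization** operates on columns, using the mean and SD
  of each voxel in a *training* sample only, so it can be applied to held-out
  data without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .inference import holm_correct

__all__ = [
    "BrainMaps",
    "OutlierResult",
    "apply_gray_mask",
    "scale_images",
    "standardize_voxels",
    "voxel_stats",
    "detect_outliers",
    "save_maps_nifti",
    "load_maps_nifti",
]


@dataclass
class BrainMaps:
    """Observations x voxels matrix with grid geometry and provenance.

    Attributes
    ----------
    data : (n_obs, n_vox) float array, signal units.
    voxel_coords : (n_vox, 3) integer grid coordinates (0-based).
    grid_shape : the full 3-D grid the coordinates live on.
    gray_mask : (n_vox,) boolean; gray-matter status of each column.
    obs_meta : one row per observation (subject, condition, trial, ...).
    provenance : ordered list of transform tags already applied.
    """

    data: np.ndarray
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    gray_mask: np.ndarray | None = None
    obs_meta: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (observations x voxels)")
        if self.voxel_coords.shape != (self.data.shape[1], 3):
            raise ValueError("voxel_coords must align with data columns")
        if self.gray_mask is None:
            self.gray_mask = np.ones(self.data.shape[1], dtype=bool)
        self.gray_mask = np.asarray(self.gray_mask, dtype=bool)
        if self.gray_mask.shape != (self.data.shape[1],):
            raise ValueError("gray_mask must have one entry per voxel")
        if self.obs_meta is not None and len(self.obs_meta) != self.data.shape[0]:
            raise ValueError("obs_meta must have one row per observation")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def select_voxels(self, index, tag: str | None = None) -> "BrainMaps":
        """New BrainMaps restricted to the voxel columns in ``index``."""
        index = np.asarray(index)
        if index.dtype == bool and index.shape != (self.n_voxels,):
            raise ValueError("boolean voxel index has wrong length")
        prov = list(self.provenance) + ([tag] if tag else [])
        return BrainMaps(
            data=self.data[:, index],
            voxel_coords=self.voxel_coords[index],
            grid_shape=self.grid_shape,
            gray_mask=self.gray_mask[index],
            obs_meta=self.obs_meta,
            provenance=prov,
        )

    def select_obs(self, index) -> "BrainMaps":
        """New BrainMaps restricted to the observation rows in ``index``."""
        meta = None if self.obs_meta is None else self.obs_meta.iloc[np.asarray(index)].reset_index(drop=True)
        return BrainMaps(
            data=self.data[np.asarray(index)],
            voxel_coords=self.voxel_coords,
            grid_shape=self.grid_shape,
            gray_mask=self.gray_mask,
            obs_meta=meta,
            provenance=list(self.provenance),
        )

    def with_data(self, data: np.ndarray, extra_tag: str | None = None) -> "BrainMaps":
        prov = list(self.provenance) + ([extra_tag] if extra_tag else [])
        return BrainMaps(
            data=data,
            voxel_coords=self.voxel_coords,
            grid_shape=self.grid_shape,
            gray_mask=self.gray_mask,
            obs_meta=self.obs_meta,
            provenance=prov,
        )


def apply_gray_mask(maps: BrainMaps, mask=None) -> BrainMaps:
    """Drop voxel columns outside the gray-matter mask.

    ``mask`` defaults to the maps' own ``gray_mask``; passing a stricter
    boolean vector supports re-evaluation under a sparser mask.
    """
    mask = maps.gray_mask if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != (maps.n_voxels,):
        raise ValueError("mask length must equal the voxel count")
    if not mask.any():
        raise ValueError("gray mask is empty")
    out = maps.select_voxels(mask, tag=f"gray_mask[{int(mask.sum())}]")
    out.gray_mask = np.ones(out.n_voxels, dtype=bool)
    return out


def scale_images(maps: BrainMaps, mode: str = "none") -> BrainMaps:
    """Image-wise scaling: per-observation centering or z-scoring.

    ``center`` subtracts each row's mean across voxels, ``zscore``
    additionally divides by the row's sample SD (n-1 convention), ``none``
    is the identity. Scaling is recorded in provenance and may be applied
    only once per map stack.
    """
    if mode not in ("none", "center", "zscore"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if any(p.startswith("scale:") for p in maps.provenance):
        raise ValueError("image-wise scaling already applied (see provenance)")
    if mode == "none":
        return maps.with_data(maps.data.copy(), extra_tag="scale:none")
    if maps.n_voxels < 2 and mode == "zscore":
        raise ValueError("zscore requires at least 2 voxels")
    mean = maps.data.mean(axis=1, keepdims=True)
    out = maps.data - mean
    if mode == "zscore":
        sd = maps.data.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise ValueError(f"zero row SD under zscore at observation(s) {bad.tolist()}")
        out = out / sd
    return maps.with_data(out, extra_tag=f"scale:{mode}")


def voxel_stats(train: BrainMaps | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel training mean and sample SD, zero-variance SDs set to 1.

    Returns the statistics used by :func:`standardize_voxels`; columns with
    zero variance get SD 1 so that standardization maps them to 0.
    """
    X = train.data if isinstance(train, BrainMaps) else np.asarray(train, float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    n_const = int(np.sum(sd == 0))
    if n_const:
        warnings.warn(
            f"{n_const} zero-variance voxel(s) set to 0 after standardization",
            stacklevel=2,
        )
        sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def standardize_voxels(train: BrainMaps, apply_to: BrainMaps | None = None) -> BrainMaps:
    """Voxel-wise z-standardization on training-sample statistics.

    Each column of ``apply_to`` (default: the training maps themselves) is
    transformed by the corresponding training-column mean and sample SD.
    Zero-variance training voxels are zeroed rather than dropped so voxel
    spaces stay aligned across pipeline stages.
    """
    if apply_to is None:
        apply_to = train
    if train.n_voxels != apply_to.n_voxels or not np.array_equal(
        train.voxel_coords, apply_to.voxel_coords
    ):
        raise ValueError("train and apply_to must share one voxel space")
    if any(p.startswith("standardize:") for p in apply_to.provenance):
        raise ValueError("voxel standardization already applied (see provenance)")
    mean, sd = voxel_stats(train)
    return apply_to.with_data((apply_to.data - mean) / sd, extra_tag="standardize:train")


@dataclass
class OutlierResult:
    """Mahalanobis outlier screen over observations."""

    d2: np.ndarray  # squared Mahalanobis distance per observation
    p: np.ndarray  # chi-square upper-tail p
    p_holm: np.ndarray
    excluded: np.ndarray  # boolean
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d2": self.d2, "p": self.p, "p_holm": self.p_holm, "excluded": self.excluded}
        )


def detect_outliers(features, alpha: float = 0.05) -> OutlierResult:
    """Multivariate outlier detection by Holm-corrected Mahalanobis distance.

    D^2 is computed against the sample mean and covariance of ``features``
    (observations x p), referred to a chi-square with p degrees of freedom,
    Holm-corrected across observations; rows with adjusted p < alpha are
    flagged for exclusion.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (observations x variables)")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than variables (n={n}, p={p})")
    centered = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        sol = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; reduce or decorrelate the feature set"
        ) from exc
    d2 = np.einsum("ij,ji->i", centered, sol)
    pvals = stats.chi2.sf(d2, df=p)
    p_holm = holm_correct(pvals)
    return OutlierResult(
        d2=d2, p=pvals, p_holm=p_holm, excluded=p_holm < alpha, alpha=alpha
    )


def save_maps_nifti(maps: BrainMaps, path) -> None:
    """Write a BrainMaps stack as one 4-D NIfTI (observation as 4th axis).

    Voxels outside the current column set are written as zero; the affine is
    identity (0-based grid indices, no resampling).
    """
    import nibabel as nib

    vol = np.zeros(maps.grid_shape + (maps.n_obs,), dtype=np.float32)
    i, j, k = maps.voxel_coords.T
    vol[i, j, k, :] = maps.data.T
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def load_maps_nifti(path, obs_meta: pd.DataFrame | None = None) -> BrainMaps:
    """Read a 4-D NIfTI stack into a BrainMaps over the full grid."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None]
    grid_shape = vol.shape[:3]
    coords = np.indices(grid_shape).reshape(3, -1).T
    data = vol.reshape(-1, vol.shape[3]).T
    return BrainMaps(
        data=data,
        voxel_coords=coords,
        grid_shape=tuple(grid_shape),
        obs_meta=obs_meta,
        provenance=[f"loaded:{path}"],
    )
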