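"""Virtual MRI phantoms: capsule voxelization, water noise, smoothing.

A root system is rendered into a 3D scalar volume whose per-voxel value
is the fraction of the voxel occupied by root tissue — each segment is a
capsule (a tube whose radius interpolates linearly between node radii,
with hemispherical caps), and occupancy is estimated with a regular
``supersampling³`` sub-grid point-in-capsule test, so the result is
deterministic.  Overlapping capsules count once (union).

Water noise emulates the blob-like spurious signal soil water produces
around roots: signed unit impulses are seeded inside a soil cylinder
(default diameter 1.5 cm) and the whole volume is then put through the
Weierstrass transform — convolution with an isotropic Gaussian — which
turns the impulses into smooth blobs.  The impulse amplitude is
calibrated so that the measured signal-to-noise ratio of the smoothed
phantom equals the configured target (default 4.3).

SNR here is contractually defined as the peak clean signal within the
dilated noise region divided by the RMS of (noisy − clean) within the
region; generator and meter share the definition, making the configured
SNR a closed-loop contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rsa import RootSystem

logger = logging.getLogger("rsaeval")

#: default isotropic voxel edge, cm (15 voxels then equal 0.75 cm)
DEFAULT_VOXEL_SIZE_CM = 0.05
#: default water-noise target SNR
DEFAULT_SNR = 4.3
#: default soil-cylinder diameter, cm
DEFAULT_CYLINDER_DIAMETER_CM = 1.5


@dataclass
class VolumeGrid:
    """Axis-aligned scalar field with isotropic voxel size (cm) and origin."""

    values: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid needs a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """World coordinates (cm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def congruent_with(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


@dataclass
class NoiseConfig:
    """Water-noise parameters; ``cylinder_center`` None means grid center."""

    snr: float = DEFAULT_SNR
    cylinder_diameter: float = DEFAULT_CYLINDER_DIAMETER_CM
    cylinder_center: tuple[float, float] | None = None  # (x, y), cm; axis along z
    impulse_density: float = 0.02
    kernel_sigma: float = 0.1  # Weierstrass bandwidth, cm
    seed: int = 0
    peak_dilation_vox: int = 3

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.cylinder_diameter <= 0:
            raise ValueError("cylinder_diameter must be positive")
        if not (0.0 < self.impulse_density <= 1.0):
            raise ValueError("impulse_density must lie in (0, 1]")
        if self.kernel_sigma < 0:
            raise ValueError("kernel_sigma must be non-negative")

    @classmethod
    def from_file(cls, path) -> "NoiseConfig":
        """Load from TOML or JSON, keyed by field name."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        if "cylinder_center" in data and data["cylinder_center"] is not None:
            data["cylinder_center"] = tuple(data["cylinder_center"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Grid construction and voxelization
# ---------------------------------------------------------------------------

def grid_for_system(
    rsa: RootSystem,
    voxel_size: float = DEFAULT_VOXEL_SIZE_CM,
    margin: float = 0.5,
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Shape and origin of the smallest grid covering the RSA plus margin."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = np.concatenate([r.positions for r in rsa.roots])
    rmax = max(n.diameter / 2 for r in rsa.roots for n in r.nodes)
    lo = pts.min(axis=0) - rmax - margin
    hi = pts.max(axis=0) + rmax + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / voxel_size)) for k in range(3))
    return shape, tuple(float(x) for x in lo)


def voxelize(
    rsa: RootSystem,
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    supersampling: int = 4,
) -> VolumeGrid:
    """Partial-volume render of an RSA onto a regular grid.

    Each voxel value is the fraction of its ``supersampling³`` sub-grid
    points falling inside the union of root capsules, clipped to [0, 1].
    Roots extending beyond the grid are clipped with a warning.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    rsa.validate()
    s = int(supersampling)
    shape = tuple(int(n) for n in shape)
    origin_a = np.asarray(origin, dtype=float)
    sub = voxel_size / s
    nsub = np.asarray(shape, dtype=np.int64) * s

    inside_flat: list[np.ndarray] = []
    clipped = False
    for root in rsa.roots:
        pos = root.positions
        radii = np.asarray([n.diameter / 2 for n in root.nodes], dtype=float)
        for i in range(len(pos) - 1):
            a, b = pos[i], pos[i + 1]
            ra, rb = radii[i], radii[i + 1]
            rmax = max(ra, rb)
            lo = np.minimum(a, b) - rmax
            hi = np.maximum(a, b) + rmax
            ilo = np.floor((lo - origin_a) / sub).astype(np.int64)
            ihi = np.ceil((hi - origin_a) / sub).astype(np.int64)
            if np.any(ihi <= 0) or np.any(ilo >= nsub):
                clipped = True
                continue
            if np.any(ilo < 0) or np.any(ihi > nsub):
                clipped = True
            ilo = np.maximum(ilo, 0)
            ihi = np.minimum(ihi, nsub)
            ax = origin_a[0] + (np.arange(ilo[0], ihi[0]) + 0.5) * sub
            ay = origin_a[1] + (np.arange(ilo[1], ihi[1]) + 0.5) * sub
            az = origin_a[2] + (np.arange(ilo[2], ihi[2]) + 0.5) * sub
            px, py, pz = np.meshgrid(ax, ay, az, indexing="ij")
            p = np.stack([px, py, pz], axis=-1)
            d = b - a
            len2 = float(d @ d)
            t = np.clip(((p - a) @ d) / len2, 0.0, 1.0)
            closest = a + t[..., None] * d
            dist2 = np.sum((p - closest) ** 2, axis=-1)
            r_t = ra + t * (rb - ra)
            mask = dist2 <= r_t * r_t
            if not mask.any():
                continue
            ix, iy, iz = np.nonzero(mask)
            flat = (
                (ix + ilo[0]) * (nsub[1] * nsub[2])
                + (iy + ilo[1]) * nsub[2]
                + (iz + ilo[2])
            )
            inside_flat.append(flat)

    if clipped:
        logger.warning("voxelize: root system extends beyond the grid; clipped")

    values = np.zeros(shape, dtype=np.float32)
    if inside_flat:
        flat = np.unique(np.concatenate(inside_flat))
        iz = flat % nsub[2]
        iy = (flat // nsub[2]) % nsub[1]
        ix = flat // (nsub[1] * nsub[2])
        vox_flat = (ix // s) * (shape[1] * shape[2]) + (iy // s) * shape[2] + (iz // s)
        counts = np.bincount(vox_flat, minlength=shape[0] * shape[1] * shape[2])
        values = (counts.reshape(shape) / float(s**3)).astype(np.float32)
        np.clip(values, 0.0, 1.0, out=values)
    return VolumeGrid(values=values, voxel_size=voxel_size, origin=tuple(origin_a))


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def cylinder_mask(volume: VolumeGrid, config: NoiseConfig) -> np.ndarray:
    """Boolean mask of the soil cylinder (axis along z) on the grid."""
    cx_arr = volume.voxel_centers_axis(0)
    cy_arr = volume.voxel_centers_axis(1)
    if config.cylinder_center is None:
        cx = 0.5 * (cx_arr[0] + cx_arr[-1])
        cy = 0.5 * (cy_arr[0] + cy_arr[-1])
    else:
        cx, cy = config.cylinder_center
    r2 = (config.cylinder_diameter / 2.0) ** 2
    in_disc = (cx_arr[:, None] - cx) ** 2 + (cy_arr[None, :] - cy) ** 2 <= r2
    if not in_disc.any():
        raise ValueError("noise cylinder lies entirely outside the grid")
    return np.broadcast_to(in_disc[:, :, None], volume.shape).copy()


def weierstrass_transform(volume: VolumeGrid, sigma: float) -> VolumeGrid:
    """Convolve with a normalized isotropic Gaussian of bandwidth sigma (cm).

    ``sigma == 0`` is the identity.  Interior-supported mass is preserved
    (zero-padded boundaries).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return VolumeGrid(
            values=volume.values.copy(),
            voxel_size=volume.voxel_size,
            origin=volume.origin,
        )
    smoothed = ndimage.gaussian_filter(
        volume.values.astype(np.float64),
        sigma=sigma / volume.voxel_size,
        mode="constant",
        truncate=5.0,
    )
    return VolumeGrid(
        values=smoothed.astype(np.float32),
        voxel_size=volume.voxel_size,
        origin=volume.origin,
    )


def measure_snr(
    clean: VolumeGrid,
    noisy: VolumeGrid,
    region: np.ndarray,
    *,
    peak_dilation_vox: int = 3,
) -> float:
    """Peak clean signal near the region over the RMS of the noise in it.

    The peak is taken over the region dilated by ``peak_dilation_vox``
    voxels; the noise is ``noisy − clean`` restricted to the region.
    Zero noise reports infinity.
    """
    if not clean.congruent_with(noisy):
        raise ValueError("clean and noisy grids are not congruent")
    region = np.asarray(region, dtype=bool)
    if region.shape != clean.shape or not region.any():
        raise ValueError("region mask must be non-empty and match the grid")
    dilated = ndimage.binary_dilation(region, iterations=peak_dilation_vox)
    peak = float(clean.values[dilated].max())
    diff = noisy.values.astype(np.float64)[region] - clean.values.astype(np.float64)[region]
    rms = float(np.sqrt(np.mean(diff**2)))
    if rms == 0.0:
        return float("inf")
    return peak / rms


def seed_water_noise(volume: VolumeGrid, config: NoiseConfig) -> VolumeGrid:
    """Seed signed water-noise impulses inside the soil cylinder.

    Impulse sites are drawn at ``impulse_density`` among cylinder voxels
    with random signs; the common amplitude is calibrated against the
    post-Weierstrass RMS of the realized impulse field so that, after
    the smoothing step, the phantom measures ``config.snr`` under
    :func:`measure_snr`.  Voxels outside the cylinder are untouched.
    Bit-reproducible from ``config.seed``.
    """
    mask = cylinder_mask(volume, config)
    rng = np.random.default_rng(config.seed)
    flat_sites = np.flatnonzero(mask.ravel())
    n_impulses = max(1, int(round(config.impulse_density * flat_sites.size)))
    chosen = rng.choice(flat_sites, size=n_impulses, replace=False)
    signs = rng.choice(np.array([-1.0, 1.0]), size=n_impulses)

    unit = np.zeros(volume.shape, dtype=np.float64)
    unit.ravel()[chosen] = signs
    unit_grid = VolumeGrid(unit, volume.voxel_size, volume.origin)
    unit_smoothed = weierstrass_transform(unit_grid, config.kernel_sigma)
    rms = float(np.sqrt(np.mean(unit_smoothed.values.astype(np.float64)[mask] ** 2)))
    if rms == 0.0:
        raise ValueError("realized noise field has zero RMS; increase density")

    clean_smoothed = weierstrass_transform(volume, config.kernel_sigma)
    dilated = ndimage.binary_dilation(mask, iterations=config.peak_dilation_vox)
    peak = float(clean_smoothed.values[dilated].max())
    if peak <= 0.0:
        raise ValueError(
            "no clean signal near the noise cylinder; SNR target is undefined"
        )
    amplitude = peak / (config.snr * rms)

    seeded = volume.values.astype(np.float64) + amplitude * unit
    return VolumeGrid(
        values=seeded.astype(np.float32),
        voxel_size=volume.voxel_size,
        origin=volume.origin,
    )


@dataclass
class Phantom:
    """Bundle of clean/noisy phantom volumes plus the noise region."""

    clean: VolumeGrid
    clean_smoothed: VolumeGrid | None
    noisy: VolumeGrid | None
    noise_region: np.ndarray | None
    config: NoiseConfig | None

    def measured_snr(self) -> float:
        if self.noisy is None or self.clean_smoothed is None:
            raise ValueError("phantom was generated without noise")
        return measure_snr(
            self.clean_smoothed,
            self.noisy,
            self.noise_region,
            peak_dilation_vox=self.config.peak_dilation_vox,
        )


def make_phantom(
    rsa: RootSystem,
    *,
    voxel_size: float = DEFAULT_VOXEL_SIZE_CM,
    margin: float = 0.5,
    supersampling: int = 4,
    noise: NoiseConfig | None = None,
) -> Phantom:
    """Voxelize an RSA and optionally add calibrated water noise.

    The noisy volume is the seeded volume after the Weierstrass
    transform; the SNR contract is measured between the smoothed clean
    volume and the smoothed noisy volume within the cylinder.
    """
    shape, origin = grid_for_system(rsa, voxel_size, margin)
    clean = voxelize(rsa, shape, voxel_size, origin, supersampling)
    if noise is None:
        return Phantom(clean, None, None, None, None)
    seeded = seed_water_noise(clean, noise)
    noisy = weierstrass_transform(seeded, noise.kernel_sigma)
    clean_smoothed = weierstrass_transform(clean, noise.kernel_sigma)
    return Phantom(clean, clean_smoothed, noisy, cylinder_mask(clean, noise), noise)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def write_volume(volume: VolumeGrid, path) -> None:
    """Write as NIfTI (.nii/.nii.gz) or raw float32 + JSON sidecar (.raw)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))
    elif path.suffix.lower() == ".raw":
        volume.values.astype("<f4").tofile(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(volume.shape),
                    "dtype": "float32",
                    "byte_order": "little",
                    "voxel_size_cm": volume.voxel_size,
                    "origin_cm": list(volume.origin),
                },
                indent=2,
            )
        )
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI or raw+sidecar volume written by :func:`write_volume`."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], atol=1e-6):
            raise ValueError(f"{path}: anisotropic voxels are not supported")
        return VolumeGrid(
            values=np.asarray(img.dataobj, dtype=np.float32),
            voxel_size=float(zooms[0]),
            origin=tuple(float(x) for x in affine[:3, 3]),
        )
    if path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: missing JSON sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        data = np.fromfile(path, dtype="<f4")
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"{path}: raw size {data.size} does not match sidecar shape {shape}"
            )
        return VolumeGrid(
            values=data.reshape(shape),
            voxel_size=float(meta["voxel_size_cm"]),
            origin=tuple(meta.get("origin_cm", (0.0, 0.0, 0.0))),
        )
    raise ValueError(f"unsupported volume format: {path.name}")
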