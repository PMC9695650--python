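"""Synthetic 3-D nodule phantoms and tabular feature cohorts.

The phantom generator emulates solitary pulmonary nodules (<= 30 mm) on an
anisotropic CT-like grid, with two classes that differ in the morphology
reported for primary lung cancer versus solitary metastasis:

* ``LM_like`` - smooth ellipsoid, homogeneous solid interior;
* ``LC_like`` - the same ellipsoid plus radial conical spicules and a
  subsolid interior (a spatially correlated fraction of interior voxels
  drawn from a ground-glass HU distribution).

Margins are never truncated: a spec whose nodule would come within 15 mm
of the grid boundary is rejected, so the perinodular ring always fits.

The tabular generator is the fast mode: two-class Gaussian feature
vectors with a chosen set of informative features shifted by stated
effect sizes (in SD units), used to exercise selection and
classification without image extraction.

Everything is deterministic given the spec seed (bit-identical outputs).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import ImageVolume, RoiMask, FeatureTable
import pandas as pd

CLASS_NAMES = ("LC_like", "LM_like")

#: required clear margin around the nodule so the perinodular ring fits, mm
SAFETY_MARGIN_MM = 15.0
#: per-axis ellipsoid radius jitter range (multiplicative)
_RADIUS_JITTER = (0.85, 1.15)
#: spicule base radius at the nodule surface, mm
_SPIKE_BASE_RADIUS_MM = 1.5
#: correlation length of the subsolid (ground-glass) interior field, mm
_SUBSOLID_CORR_MM = 3.0


@dataclass
class PhantomSpec:
    """Parameters of a two-class phantom cohort.

    HU defaults follow plausible chest-CT ranges: solid tissue 50 +/- 15,
    ground-glass -450 +/- 60, aerated lung background -850 +/- 40.
    Spacing default (0.7, 0.7, 2.5) mm mirrors thick-slice chest
    reconstructions.
    """

    n_per_class: int = 100
    grid_shape: tuple[int, int, int] = (96, 96, 28)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 2.5)
    base_radius_mm: float = 7.0
    class_A_spikes: int = 8
    spike_length_mm: float = 5.0
    class_A_subsolid_fraction: float = 0.4
    hu_solid_mean: float = 50.0
    hu_solid_sd: float = 15.0
    hu_groundglass_mean: float = -450.0
    hu_groundglass_sd: float = 60.0
    hu_background_mean: float = -850.0
    hu_background_sd: float = 40.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacings must be > 0")
        if not (3.0 < self.base_radius_mm <= 15.0):
            raise ValueError("base_radius_mm must lie in (3, 15] (nodule < 30 mm)")
        if not (0.0 <= self.class_A_subsolid_fraction <= 1.0):
            raise ValueError("class_A_subsolid_fraction must lie in [0, 1]")
        if self.class_A_spikes < 0 or self.spike_length_mm < 0 or self.noise_sd < 0:
            raise ValueError("spikes, spike_length_mm and noise_sd must be >= 0")
        max_extent = self.base_radius_mm * _RADIUS_JITTER[1] + (
            self.spike_length_mm if self.class_A_spikes > 0 else 0.0
        )
        for n, s in zip(self.grid_shape, self.spacing_mm):
            half = (n - 1) * s / 2.0
            if max_extent + SAFETY_MARGIN_MM > half:
                raise ValueError(
                    f"nodule (extent {max_extent:.1f} mm) would violate the "
                    f"{SAFETY_MARGIN_MM:.0f} mm margin on an axis with half-extent "
                    f"{half:.1f} mm; enlarge the grid"
                )


def _physical_axes(spec: PhantomSpec):
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]


def generate_phantom(
    spec: PhantomSpec, case_class: str, case_index: int = 0
) -> tuple[ImageVolume, RoiMask, dict]:
    """Generate one phantom volume with its ground-truth nodule mask.

    The mask is computed before noise is added (no segmentation-error
    model).  ``case_index`` varies the per-case randomness; the triple
    (seed, class, index) fully determines the output bit-for-bit.

    Returns ``(volume, intra_mask, semantic_labels)`` where the labels
    record the generating class and the spiculated / subsolid flags.
    """
    if case_class not in CLASS_NAMES:
        raise ValueError(f"case_class must be one of {CLASS_NAMES}")
    is_lc = case_class == "LC_like"
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, CLASS_NAMES.index(case_class), case_index])
    )
    xs, ys, zs = _physical_axes(spec)
    gx = xs[:, None, None]
    gy = ys[None, :, None]
    gz = zs[None, None, :]

    center = rng.uniform(-0.5, 0.5, 3) * np.asarray(spec.spacing_mm)
    radii = spec.base_radius_mm * rng.uniform(*_RADIUS_JITTER, size=3)
    px, py, pz = gx - center[0], gy - center[1], gz - center[2]
    mask = (px / radii[0]) ** 2 + (py / radii[1]) ** 2 + (pz / radii[2]) ** 2 <= 1.0

    spiculated = is_lc and spec.class_A_spikes > 0 and spec.spike_length_mm > 0
    if spiculated:
        for _ in range(spec.class_A_spikes):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # ellipsoid radius along u
            r_u = 1.0 / np.sqrt(np.sum((u / radii) ** 2))
            s = px * u[0] + py * u[1] + pz * u[2]
            perp2 = (px**2 + py**2 + pz**2) - s**2
            taper = 1.0 - np.clip(s - r_u, 0.0, None) / spec.spike_length_mm
            limit = _SPIKE_BASE_RADIUS_MM * np.clip(taper, 0.0, None)
            cone = (s >= 0.5 * r_u) & (s <= r_u + spec.spike_length_mm)
            mask |= cone & (perp2 <= limit**2)

    volume = rng.normal(spec.hu_background_mean, spec.hu_background_sd, spec.grid_shape)
    interior = rng.normal(spec.hu_solid_mean, spec.hu_solid_sd, spec.grid_shape)
    volume[mask] = interior[mask]

    subsolid = is_lc and spec.class_A_subsolid_fraction > 0
    if subsolid:
        # spatially correlated ground-glass pockets covering the stated
        # fraction of interior voxels
        field = gaussian_filter(
            rng.normal(size=spec.grid_shape),
            sigma=[_SUBSOLID_CORR_MM / s for s in spec.spacing_mm],
        )
        inside_vals = field[mask]
        cut = np.quantile(inside_vals, spec.class_A_subsolid_fraction)
        gg = mask & (field <= cut)
        volume[gg] = rng.normal(spec.hu_groundglass_mean, spec.hu_groundglass_sd, spec.grid_shape)[gg]

    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    labels = {
        "class": "LC" if is_lc else "LM",
        "spiculated": bool(spiculated),
        "subsolid": bool(subsolid),
    }
    image = ImageVolume(voxels=volume, spacing_mm=spec.spacing_mm)
    return image, RoiMask(voxels=mask, role="intra"), labels


def generate_cohort(spec: PhantomSpec):
    """Yield ``(case_id, case_class, volume, mask, labels)`` for the cohort.

    Cases alternate LC_like / LM_like per index so truncated prefixes stay
    balanced.
    """
    for i in range(spec.n_per_class):
        for case_class in CLASS_NAMES:
            case_id = f"{case_class[:2]}{i:04d}"
            vol, mask, labels = generate_phantom(spec, case_class, case_index=i)
            yield case_id, case_class, vol, mask, labels


def write_cohort(spec: PhantomSpec, out_dir: str | Path, fmt: str = "nrrd") -> Path:
    """Write paired volume/mask files (HU int16 / uint8) plus a cohort CSV."""
    from .volume_io import write_volume, write_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = out_dir / "cohort.csv"
    with open(sheet, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "class", "spiculated", "subsolid", "volume", "mask"])
        for case_id, _, vol, mask, labels in generate_cohort(spec):
            vol_path = out_dir / f"{case_id}_vol.{fmt}"
            mask_path = out_dir / f"{case_id}_mask.{fmt}"
            quantised = ImageVolume(
                voxels=np.round(vol.voxels).astype(np.int16),
                spacing_mm=vol.spacing_mm,
                origin_mm=vol.origin_mm,
            )
            write_volume(quantised, vol_path)
            write_mask(mask, vol, mask_path)
            writer.writerow(
                [case_id, labels["class"], int(labels["spiculated"]),
                 int(labels["subsolid"]), vol_path.name, mask_path.name]
            )
    return sheet


# ---------------------------------------------------------------------------
# Fast tabular mode
# ---------------------------------------------------------------------------

@dataclass
class TabularSpec:
    """Two-class Gaussian feature table with planted informative features.

    ``effect_sizes`` are mean shifts of the LC class in SD units, one per
    informative index.  ``correlation`` is the equicorrelation of features
    within a class.
    """

    n_per_class: int
    n_features: int
    informative_indices: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.informative_indices = tuple(int(i) for i in self.informative_indices)
        self.effect_sizes = tuple(float(e) for e in self.effect_sizes)
        if len(self.informative_indices) != len(self.effect_sizes):
            raise ValueError("informative_indices and effect_sizes must pair up")
        if any(not (0 <= i < self.n_features) for i in self.informative_indices):
            raise ValueError("informative_indices out of range")
        if any(not np.isfinite(e) for e in self.effect_sizes):
            raise ValueError("effect sizes must be finite")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")


def generate_feature_table(spec: TabularSpec) -> FeatureTable:
    """Draw the two-class Gaussian table described by ``spec``.

    Noise features are N(0, 1); informative features in the LC class are
    shifted by their effect sizes.  Equicorrelation is induced by a shared
    per-case latent factor, keeping unit marginal variance.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = 2 * spec.n_per_class, spec.n_features
    shared = rng.normal(size=(n, 1))
    indiv = rng.normal(size=(n, p))
    rho = spec.correlation
    x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
    labels = np.array(["LC"] * spec.n_per_class + ["LM"] * spec.n_per_class)
    for idx, eff in zip(spec.informative_indices, spec.effect_sizes):
        x[labels == "LC", idx] += eff
    df = pd.DataFrame(x, columns=[f"f{i:03d}" for i in range(p)])
    df.insert(0, "case_id", [f"case{i:04d}" for i in range(n)])
    df.insert(1, "label", labels)
    df.insert(2, "split", "train")
    return FeatureTable(df)
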