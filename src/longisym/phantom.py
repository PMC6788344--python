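"""Synthetic longitudinal atrophy phantoms.

Generates seeded cohorts of paired 3-D "brain" volumes emulating the data a
longitudinal structural study works with: two sessions per subject, a toy
integer-label atlas, class-dependent regional intensity loss between the
sessions (progressor-like atrophy, non-progressor near-zero change, and an
intermediate class), additive Gaussian noise, and a small rigid misalignment
of the second session.

Design of the phantom:

* The "brain" is an axis-aligned ellipsoid at 80% of the grid extent, giving
  a guaranteed empty background for the cropping stage.
* Regions are a seeded Voronoi partition of the brain mask grown from random
  interior sites; Voronoi cells of a convex mask are connected.
* Atrophy is multiplicative intensity loss in designated target regions
  (session2 = (1 - fraction) * session1 there), so the implanted ground
  truth is analytically recoverable from noiseless aligned pairs.
* Session-2 corruption order is atrophy -> rigid perturbation -> noise, so
  registration has to be solved before change detection, as in real
  longitudinal pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .volume import RigidTransform, Volume

__all__ = [
    "PhantomConfig",
    "ToyAtlas",
    "SubjectRecord",
    "build_atlas",
    "generate_cohort",
    "write_cohort_bids",
    "load_cohort_bids",
]

#: Class labels in canonical order.
CLASSES = ("non-progressor", "progressor", "intermediate")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for a synthetic longitudinal cohort.

    Defaults describe a desk-scale cohort: a 16^3 isotropic 1 mm grid, six
    Voronoi regions inside an ellipsoidal brain mask, 40% intensity loss in
    region 3 for progressors, 20% for the intermediate class, additive noise
    with SD 5% of the intensity range, and up to 2 mm / 2 deg of rigid
    misalignment of the second session.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 6
    class_atrophy_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "progressor": 0.4,
            "non-progressor": 0.0,
            "intermediate": 0.2,
        }
    )
    target_regions: tuple[int, ...] = (3,)
    noise_sd: float = 0.05
    misalign_max: tuple[float, float] = (2.0, 2.0)  # (|translation| mm, |rotation| deg)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 8 for g in self.grid_shape):
            raise ConfigurationError(
                f"grid_shape must be 3 integers >= 8, got {self.grid_shape}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing_mm}")
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        for key in ("progressor", "non-progressor"):
            if key not in self.class_atrophy_fraction:
                raise ConfigurationError(
                    f"class_atrophy_fraction must contain '{key}'"
                )
        for cls, frac in self.class_atrophy_fraction.items():
            if not (0.0 <= frac < 1.0):
                raise ConfigurationError(
                    f"atrophy fraction for {cls!r} must be in [0, 1), got {frac}"
                )
        if not set(self.target_regions) <= set(range(1, self.n_regions + 1)):
            raise ConfigurationError(
                f"target_regions {self.target_regions} not within region ids "
                f"1..{self.n_regions}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(m < 0 for m in self.misalign_max):
            raise ConfigurationError("misalign_max components must be >= 0")


@dataclass
class ToyAtlas:
    """Integer-label region atlas; label 0 is background."""

    labels: Volume
    region_names: dict[int, str]
    region_volumes: dict[int, int]
    region_groups: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels.data).astype(int)) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ConfigurationError(f"labels {sorted(missing)} lack region names")
        for r, v in self.region_volumes.items():
            count = int(np.sum(self.labels.data == r))
            if count != v or v <= 0:
                raise ConfigurationError(
                    f"region_volumes[{r}]={v} does not match voxel count {count}"
                )

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_volumes)


@dataclass
class SubjectRecord:
    """One synthetic subject: two sessions, class label, and ground truth."""

    subject_id: str
    class_label: str
    session1: Volume
    session2: Volume
    true_transform: RigidTransform
    true_atrophy_fraction: float
    covariates: dict[str, float] = field(default_factory=dict)


def _ellipsoid_mask(shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned ellipsoid at 80% of the grid extent."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.8 * n / 2.0 for n in shape]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return q <= 1.0


def build_atlas(config: PhantomConfig) -> ToyAtlas:
    """Seeded Voronoi partition of the ellipsoidal brain mask into regions."""
    rng = np.random.default_rng([config.seed, 101])
    mask = _ellipsoid_mask(config.grid_shape, config.spacing_mm)
    coords = np.argwhere(mask)
    if len(coords) < config.n_regions:
        raise ConfigurationError(
            f"grid {config.grid_shape} too small to host {config.n_regions} regions"
        )
    sites = coords[rng.choice(len(coords), size=config.n_regions, replace=False)]
    # Nearest-site labelling in physical (mm) coordinates.
    spacing = np.asarray(config.spacing_mm)
    d2 = np.sum(
        ((coords[:, None, :] - sites[None, :, :]) * spacing) ** 2, axis=2
    )
    nearest = np.argmin(d2, axis=1) + 1
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    labels[tuple(coords.T)] = nearest
    ids = sorted(set(range(1, config.n_regions + 1)) & set(np.unique(nearest)))
    names = {r: f"region-{r:02d}" for r in ids}
    volumes = {r: int(np.sum(labels == r)) for r in ids}
    groups = {r: ("subcortical" if r % 2 else "cortical") for r in ids}
    return ToyAtlas(
        labels=Volume(labels, config.spacing_mm),
        region_names=names,
        region_volumes=volumes,
        region_groups=groups,
    )


def _base_brain(
    shape: tuple[int, int, int],
    labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subject anatomy: tissue-like region contrast plus a smooth random field.

    Each atlas region gets a distinct mean intensity (as tissue classes do),
    which also makes the rigid-alignment problem well conditioned; a smooth
    subject-specific field adds anatomical variability.
    """
    mask = labels > 0
    g = gaussian_filter(rng.normal(size=shape), sigma=2.0)
    sd = g.std()
    if sd > 0:
        g = g / sd
    offsets = np.array([0.0, -0.15, 0.0, 0.15])  # cycled over region ids
    tissue = 0.6 + gaussian_filter(offsets[np.maximum(labels, 0) % 4], 1.0) + 0.08 * g
    tissue = np.clip(tissue, 0.25, 1.0)
    # Taper the brain edge slightly (partial-volume-like); smooth boundaries
    # keep resampling interpolation error small without blurring away the
    # tissue contrast that makes rigid alignment well conditioned.
    envelope = gaussian_filter(mask.astype(float), sigma=0.5)
    peak = envelope.max()
    if peak > 0:
        envelope = np.clip(envelope / peak, 0.0, 1.0)
    return tissue * envelope


def generate_cohort(
    config: PhantomConfig,
    n_per_class: dict[str, int],
) -> tuple[ToyAtlas, list[SubjectRecord]]:
    """Generate a seeded cohort of longitudinal pairs.

    Session 1 is the subject's base brain plus noise; session 2 applies the
    class's atrophy fraction to the target regions, a random rigid
    perturbation bounded by ``misalign_max``, then independent noise.
    """
    from .preproc import resample  # local import to avoid a cycle

    atlas = build_atlas(config)
    mask = atlas.labels.data > 0
    target = np.isin(atlas.labels.data, list(config.target_regions))
    records: list[SubjectRecord] = []
    tmax, rmax = config.misalign_max
    for cls_idx, cls in enumerate(sorted(n_per_class)):
        if cls not in config.class_atrophy_fraction:
            raise ConfigurationError(f"no atrophy fraction configured for class {cls!r}")
        frac = config.class_atrophy_fraction[cls]
        for i in range(n_per_class[cls]):
            rng = np.random.default_rng([config.seed, 202, cls_idx, i])
            base = _base_brain(config.grid_shape, atlas.labels.data, rng)
            s1 = base.copy()
            atrophied = base.copy()
            atrophied[target] *= 1.0 - frac
            vol1 = Volume(s1, config.spacing_mm)
            center = tuple(vol1.world_center())
            transform = RigidTransform(
                rotations_deg=tuple(rng.uniform(-rmax, rmax, size=3)),
                translations_mm=tuple(rng.uniform(-tmax, tmax, size=3)),
                center=center,
            )
            if transform.is_identity():
                s2 = atrophied
            else:
                # Cubic interpolation keeps the synthetic acquisition sharp,
                # as two separately acquired sessions would both be.
                s2 = resample(
                    Volume(atrophied, config.spacing_mm), transform, vol1, "cubic"
                ).data
            if config.noise_sd > 0:
                s1 = s1 + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
                s2 = s2 + rng.normal(0.0, config.noise_sd, size=config.grid_shape)
            covariates = {
                "time_between_sessions_years": float(rng.uniform(0.5, 2.5)),
                "gender": int(rng.integers(0, 2)),
                "age": float(rng.normal(74.0, 6.0)),
            }
            records.append(
                SubjectRecord(
                    subject_id=f"{cls_idx}{i:04d}",
                    class_label=cls,
                    session1=Volume(s1, config.spacing_mm),
                    session2=Volume(s2, config.spacing_mm),
                    true_transform=transform,
                    true_atrophy_fraction=frac,
                    covariates=covariates,
                )
            )
    return atlas, records


# ---- BIDS-like on-disk layout ------------------------------------------------


def write_cohort_bids(out_dir: str | Path, atlas: ToyAtlas, records: list[SubjectRecord]) -> Path:
    """Write a cohort as ``sub-<id>/ses-<k>/anat/*_T1w.nii.gz`` plus sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for ses, vol in ((1, rec.session1), (2, rec.session2)):
            anat = out / f"sub-{rec.subject_id}" / f"ses-{ses}" / "anat"
            anat.mkdir(parents=True, exist_ok=True)
            vol.save(anat / f"sub-{rec.subject_id}_ses-{ses}_T1w.nii.gz")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "class_label": rec.class_label,
                "true_atrophy_fraction": rec.true_atrophy_fraction,
                **rec.covariates,
            }
        )
        meta = {
            "true_transform": {
                "rotations_deg": list(rec.true_transform.rotations_deg),
                "translations_mm": list(rec.true_transform.translations_mm),
                "center": list(rec.true_transform.center),
            }
        }
        (out / f"sub-{rec.subject_id}" / "truth.json").write_text(json.dumps(meta, indent=1))
    pd.DataFrame(rows).to_csv(out / "participants.tsv", sep="\t", index=False)
    atlas.labels.save(out / "atlas.nii.gz")
    pd.DataFrame(
        {
            "region_id": atlas.region_ids,
            "name": [atlas.region_names[r] for r in atlas.region_ids],
            "group": [atlas.region_groups.get(r, "") for r in atlas.region_ids],
        }
    ).to_csv(out / "atlas_labels.tsv", sep="\t", index=False)
    return out


def load_cohort_bids(in_dir: str | Path) -> tuple[ToyAtlas, list[SubjectRecord]]:
    """Read back a cohort written by :func:`write_cohort_bids`."""
    root = Path(in_dir)
    labels_vol = Volume.load(root / "atlas.nii.gz")
    labels_vol = labels_vol.like(np.rint(labels_vol.data).astype(np.int16))
    tab = pd.read_csv(root / "atlas_labels.tsv", sep="\t")
    names = dict(zip(tab["region_id"].astype(int), tab["name"]))
    groups = dict(zip(tab["region_id"].astype(int), tab.get("group", "")))
    volumes = {r: int(np.sum(labels_vol.data == r)) for r in names}
    atlas = ToyAtlas(labels_vol, names, volumes, groups)
    participants = pd.read_csv(root / "participants.tsv", sep="\t", dtype={"subject_id": str})
    records = []
    for _, row in participants.iterrows():
        sid = str(row["subject_id"])
        vols = {}
        for ses in (1, 2):
            p = root / f"sub-{sid}" / f"ses-{ses}" / "anat" / f"sub-{sid}_ses-{ses}_T1w.nii.gz"
            vols[ses] = Volume.load(p)
        truth_path = root / f"sub-{sid}" / "truth.json"
        transform = RigidTransform()
        if truth_path.exists():
            t = json.loads(truth_path.read_text())["true_transform"]
            transform = RigidTransform(
                tuple(t["rotations_deg"]), tuple(t["translations_mm"]), tuple(t["center"])
            )
        covariates = {
            k: row[k]
            for k in ("time_between_sessions_years", "gender", "age")
            if k in row
        }
        records.append(
            SubjectRecord(
                subject_id=sid,
                class_label=str(row["class_label"]),
                session1=vols[1],
                session2=vols[2],
                true_transform=transform,
                true_atrophy_fraction=float(row.get("true_atrophy_fraction", np.nan)),
                covariates=covariates,
            )
        )
    return atlas, records
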