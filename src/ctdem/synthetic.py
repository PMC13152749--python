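"""Synthetic inputs: oracle fields, canonical fractal sets, lesion phantoms.

Everything the pipeline consumes can be generated here without any download:

* quadratic scalar fields with closed-form gradient/Hessian, for verifying
  the elasticity response and its affine invariance;
* canonical voxel sets of known fractal dimension (cube 3, plane 2, line 1,
  Menger sponge log20/log3);
* two-class ellipsoidal lymph-node phantoms on a CT-like background, whose
  internal texture is a sum of Gaussian random fields — the metastatic-like
  class mixes several correlation lengths at higher amplitude, producing the
  higher DEM entropy and fractal dimension the analysis is designed to
  detect;
* a covariate table with the structure of a baseline-characteristics table.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = [
    "QuadraticOracle",
    "make_quadratic_field",
    "make_fractal_set",
    "PhantomSpec",
    "CohortSpec",
    "benign_spec",
    "metastatic_spec",
    "make_lesion",
    "make_cohort",
    "table1_contingency",
    "make_covariate_table",
]


# ---------------------------------------------------------------------------
# analytic oracle fields


@dataclass
class QuadraticOracle:
    """Closed-form derivatives of I(x) = xᵀMx + bᵀx + c on a centred grid."""

    M: np.ndarray
    b: np.ndarray
    c: float
    shape: tuple[int, int, int]

    def centred_coords(self) -> np.ndarray:
        """(…, 3) array of grid coordinates with the origin at the centre."""
        axes = [np.arange(n) - (n - 1) / 2.0 for n in self.shape]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * np.einsum("ij,...j->...i", self.M, x) + self.b

    def hessian(self, x: np.ndarray) -> np.ndarray:
        H = 2.0 * self.M
        return np.broadcast_to(H, np.shape(x)[:-1] + (3, 3)).copy()

    def gradient_field(self) -> np.ndarray:
        return self.gradient(self.centred_coords())

    def hessian_field(self) -> np.ndarray:
        return self.hessian(self.centred_coords())


def make_quadratic_field(M, b=(0.0, 0.0, 0.0), c: float = 0.0, shape=(16, 16, 16)):
    """Quadratic scalar field with its exact derivative oracle.

    Returns ``(ImageVolume, QuadraticOracle)``.  Voxel values are
    I(x) = xᵀMx + bᵀx + c on a grid centred at the volume centre; the oracle
    returns the exact gradient 2Mx + b and constant Hessian 2M.
    """
    M = np.asarray(M, dtype=float)
    b = np.asarray(b, dtype=float)
    if M.shape != (3, 3) or not np.allclose(M, M.T):
        raise ValueError("M must be a symmetric 3x3 matrix")
    if any(n < 8 for n in shape):
        raise ValueError("shape must be at least (8, 8, 8)")
    oracle = QuadraticOracle(M, b, float(c), tuple(shape))
    x = oracle.centred_coords()
    vals = np.einsum("...i,ij,...j->...", x, M, x) + x @ b + c
    return ImageVolume(vals), oracle


# ---------------------------------------------------------------------------
# canonical fractal sets


def _menger(level: int) -> np.ndarray:
    m = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        k = m.shape[0]
        out = np.zeros((3 * k,) * 3, dtype=bool)
        for i, j, l in itertools.product(range(3), repeat=3):
            if (i == 1) + (j == 1) + (l == 1) >= 2:
                continue
            out[i * k : (i + 1) * k, j * k : (j + 1) * k, l * k : (l + 1) * k] = m
        m = out
    return m


def make_fractal_set(kind: str, size: int = 32, level: int = 3) -> BinaryMask:
    """Canonical binary sets with known limit dimension.

    ``cube`` (dimension 3), ``plane`` (2), ``line`` (1) at the given
    ``size``; ``menger`` builds the level-``level`` sponge on a 3**level
    lattice (dimension log 20 / log 3 ≈ 2.727).
    """
    if kind == "cube":
        data = np.ones((size,) * 3, dtype=bool)
    elif kind == "plane":
        data = np.zeros((size, size, 4), dtype=bool)
        data[:, :, 0] = True
    elif kind == "line":
        data = np.zeros((size, 4, 4), dtype=bool)
        data[:, 0, 0] = True
    elif kind == "menger":
        data = _menger(level)
    else:
        raise ValueError(f"unsupported fractal set kind {kind!r}")
    return BinaryMask(data)


# ---------------------------------------------------------------------------
# lesion phantoms


@dataclass
class PhantomSpec:
    """One synthetic lymph-node lesion on a CT-like background.

    The ellipsoidal node (semi-axes in voxels, ≥ 2) sits on a background of
    ``background_level`` HU with white noise; its interior intensity is
    ``lesion_level`` plus a sum of Gaussian-random-field texture components,
    each a (correlation length voxels, amplitude HU) pair.  Class label 1 is
    metastatic-like.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] = (9.0, 10.0, 11.0)
    background_level: float = 25.0
    background_noise_sd: float = 5.0
    lesion_level: float = 45.0
    texture: tuple[tuple[float, float], ...] = ((4.0, 2.5),)
    label: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 2 for a in self.semi_axes):
            raise ValueError("semi-axes must be at least 2 voxels")
        if any(a < 0 for _, a in self.texture):
            raise ValueError("texture amplitudes must be non-negative")
        c = self.center if self.center is not None else tuple((n - 1) / 2.0 for n in self.shape)
        if any(
            c[i] - self.semi_axes[i] < 0 or c[i] + self.semi_axes[i] > self.shape[i] - 1
            for i in range(3)
        ):
            raise ValueError("lesion exceeds the grid")
        self.center = tuple(float(v) for v in c)


def benign_spec(**overrides) -> PhantomSpec:
    """Benign-like template: one smooth, low-amplitude texture component."""
    return PhantomSpec(texture=((4.0, 2.5),), label=0, **overrides)


def metastatic_spec(**overrides) -> PhantomSpec:
    """Metastatic-like template: three correlation lengths, higher amplitude.

    The mixed scales (1, 2 and 4 voxels) emulate the disrupted multi-scale
    architecture of infiltrated nodes and raise both DEM entropy and the
    fractal-dimension aggregates relative to the benign template.
    """
    return PhantomSpec(texture=((1.0, 16.0), (2.0, 12.0), (4.0, 10.0)), label=1, **overrides)



def _grf(shape, corr_len, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma=corr_len, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_lesion(spec: PhantomSpec):
    """Render one phantom; returns ``(ImageVolume, BinaryMask, label)``.

    Bitwise reproducible for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    vol = spec.background_level + spec.background_noise_sd * rng.standard_normal(spec.shape)
    axes = [np.arange(n) for n in spec.shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = spec.center
    ax, ay, az = spec.semi_axes
    inside = ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0
    tex = np.zeros(spec.shape)
    for corr_len, amp in spec.texture:
        if amp == 0:
            continue
        tex += amp * _grf(spec.shape, corr_len, rng)
    vol[inside] = spec.lesion_level + tex[inside]
    spacing = spec.spacing
    return ImageVolume(vol, spacing), BinaryMask(inside, spacing), int(spec.label)


@dataclass
class CohortSpec:
    """A two-class phantom cohort with geometric jitter.

    ``jitter_axes`` / ``jitter_center`` are half-widths (voxels) of uniform
    perturbations applied per lesion; ``master_seed`` drives every random
    choice.
    """

    n_pos: int = 30
    n_neg: int = 30
    positive_template: PhantomSpec = field(default_factory=metastatic_spec)
    negative_template: PhantomSpec = field(default_factory=benign_spec)
    jitter_axes: float = 2.0
    jitter_center: float = 3.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one lesion")


def _jittered(template: PhantomSpec, rng, seed: int, j_axes: float, j_center: float) -> PhantomSpec:
    axes = tuple(max(2.0, a + rng.uniform(-j_axes, j_axes)) for a in template.semi_axes)
    base_center = tuple((n - 1) / 2.0 for n in template.shape)
    center = tuple(
        float(np.clip(c + rng.uniform(-j_center, j_center), ax + 1, n - ax - 2))
        for c, ax, n in zip(base_center, axes, template.shape)
    )
    return replace(template, semi_axes=axes, center=center, seed=seed)


def make_cohort(spec: CohortSpec, out_dir=None):
    """Generate a labelled phantom cohort.

    Returns ``(lesions, manifest)``: a list of (volume, mask, label) triples
    and a manifest DataFrame (case_id, label and, when ``out_dir`` is given,
    the written NIfTI paths).  The covariate table is produced separately by
    :func:`make_covariate_table`.
    """
    from .volume import write_mask, write_volume

    ss = np.random.SeedSequence(spec.master_seed)
    n = spec.n_pos + spec.n_neg
    children = ss.spawn(n)
    lesions = []
    rows = []
    for i in range(n):
        label = 1 if i < spec.n_pos else 0
        template = spec.positive_template if label else spec.negative_template
        rng = np.random.default_rng(children[i])
        lesion_seed = int(rng.integers(0, 2**31 - 1))
        ps = _jittered(template, rng, lesion_seed, spec.jitter_axes, spec.jitter_center)
        ps = replace(ps, label=label)
        vol, mask, _ = make_lesion(ps)
        case_id = f"case_{i:03d}"
        row = {"case_id": case_id, "label": label}
        if out_dir is not None:
            import os

            os.makedirs(out_dir, exist_ok=True)
            vp = os.path.join(out_dir, f"{case_id}_ct.nii.gz")
            mp = os.path.join(out_dir, f"{case_id}_mask.nii.gz")
            write_volume(vol, vp)
            write_mask(mask, mp)
            row["volume_path"] = vp
            row["mask_path"] = mp
        lesions.append((vol, mask, label))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import os

        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return lesions, manifest


# ---------------------------------------------------------------------------
# covariate fixtures


def table1_contingency() -> dict[str, np.ndarray]:
    """Printed baseline contingency tables (rows = categories, cols = label 0/1).

    These reproduce the published cohort's categorical counts and serve as
    fixed inputs for the categorical-test routines.
    """
    return {
        "gender": np.array([[229, 101], [53, 32]]),  # male, female
        "smoking": np.array([[196, 87], [86, 46]]),  # no, yes
        "location": np.array([[12, 10], [187, 90], [83, 33]]),  # upper, middle, lower
        "differentiation": np.array([[7, 17], [262, 109], [13, 7]]),  # low, medium, high
    }


def make_covariate_table(n_pos: int, n_neg: int, seed: int = 0) -> pd.DataFrame:
    """Per-lesion clinical covariates sampled to match the printed marginals.

    Categorical covariates are drawn with the class-conditional proportions
    of :func:`table1_contingency`; age is normal (61.9 ± 8.2 years).
    """
    rng = np.random.default_rng(seed)
    tabs = table1_contingency()
    rows = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        col = 1 if label else 0
        rec = {"case_id": f"case_{i:03d}", "label": label}
        rec["age"] = float(rng.normal(61.9, 8.2))
        for name, levels in (
            ("gender", ["male", "female"]),
            ("smoking", ["no", "yes"]),
            ("location", ["upper", "middle", "lower"]),
            ("differentiation", ["low", "medium", "high"]),
        ):
            probs = tabs[name][:, col] / tabs[name][:, col].sum()
            rec[name] = str(rng.choice(levels, p=probs))
        rows.append(rec)
    return pd.DataFrame(rows)
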