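"""Synthetic 3D stacks with ground-truth vesicle annotations.

Generates single-cell z-stacks emulating EEA1-like punctate staining so that
every pipeline stage can be exercised without microscope data. A cell is an
axially squashed ball (adherent-cell geometry; the isotropic limit at
squash 1.0 recovers the spherical closed forms). Vesicle centres follow one
of three spatial models:

``uniform_ball``
    Homogeneous dispersion through the cell volume — the wild-type-like
    phenotype with a unimodal distance distribution.
``shell``
    Uniform in a thin shell at the cell radius — a pure plasma-membrane
    phenotype.
``bimodal``
    Mixture of a perinuclear core (isotropic Gaussian truncated to the
    ball) and the membrane shell — the mutant-like phenotype whose scaled
    distance distribution is bimodal. ``membrane_weight`` sets the shell
    mixture weight (0.5 mutant-like, ~0.1 for a pharmacological rescue,
    0 degenerates to the pure core).

Each vesicle is rendered as an amplitude-jittered Gaussian spot of width
``psf_sigma`` (confocal-like 2.5 px, STED-like 0.6 px); Gaussian camera
background is added, and the result is clipped at zero and quantized to
16 bits. Rendering consumes no randomness after the centres and amplitudes
are drawn, so two specs differing only in ``psf_sigma`` share identical
ground truth — the basis of STED-vs-confocal resolution comparisons.

Deterministic noise-free phantoms (:func:`ball_phantom`,
:func:`shell_phantom`) realize the continuum limits used for analytic
validation: a uniform ball has R_g = sqrt(3/5) R and scaled-distance
density 3 s^2 / s_max^3 with s_max = sqrt(5/3); a thin shell has R_g = R
and all scaled mass at s = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import ImageStack

__all__ = [
    "SyntheticCellSpec",
    "generate_cell",
    "generate_population",
    "ball_phantom",
    "shell_phantom",
]

# Gaussian camera background matching a typical 16-bit confocal detector.
DEFAULT_BACKGROUND_MU = 1861.63
DEFAULT_BACKGROUND_SIGMA = 147.70

SPATIAL_MODELS = ("uniform_ball", "bimodal", "shell")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of one synthetic cell.

    ``cell_radius`` is the in-plane radius in pixels; the axial semi-axis is
    ``axial_squash * cell_radius`` (isotropic at 1.0). ``perinuclear_radius``
    defaults to 0.35 x cell_radius and ``vesicle_amplitude`` (mean peak
    intensity above background) to 20 x background_sigma. Defaults are sized
    so the squashed cell fits the stack with margin.
    """

    shape: tuple[int, int, int] = (64, 160, 160)
    cell_radius: float = 50.0
    axial_squash: float = 0.5
    n_vesicles: int = 150
    spatial_model: str = "uniform_ball"
    membrane_weight: float = 0.0
    shell_thickness: float = 4.0
    perinuclear_radius: float | None = None
    psf_sigma: float = 2.5
    vesicle_amplitude: float | None = None
    amplitude_jitter: float = 0.3
    background_mu: float = DEFAULT_BACKGROUND_MU
    background_sigma: float = DEFAULT_BACKGROUND_SIGMA
    seed: int = 0
    cell_id: str = ""
    group: str = ""

    def __post_init__(self):
        if self.spatial_model not in SPATIAL_MODELS:
            raise ValueError(f"spatial_model must be one of {SPATIAL_MODELS}")
        if not 0.0 <= self.membrane_weight <= 1.0:
            raise ValueError("membrane_weight must lie in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if not 0.0 < self.axial_squash <= 1.0:
            raise ValueError("axial_squash must lie in (0, 1]")
        if self.n_vesicles < 1:
            raise ValueError("n_vesicles must be >= 1")
        if not 0.0 <= self.amplitude_jitter < 1.0:
            raise ValueError("amplitude_jitter must lie in [0, 1)")
        nz, ny, nx = self.shape
        if (
            self.axial_squash * self.cell_radius > (nz - 1) / 2
            or self.cell_radius > (ny - 1) / 2
            or self.cell_radius > (nx - 1) / 2
        ):
            raise ValueError("cell does not fit inside the stack bounds")

    @property
    def core_radius(self) -> float:
        return (
            0.35 * self.cell_radius
            if self.perinuclear_radius is None
            else self.perinuclear_radius
        )

    @property
    def amplitude(self) -> float:
        return (
            20.0 * self.background_sigma
            if self.vesicle_amplitude is None
            else self.vesicle_amplitude
        )

    @property
    def stack_center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=np.float64) - 1.0) / 2.0


def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return _unit_directions(rng, n) * r[:, None]


def _sample_shell(
    rng: np.random.Generator, n: int, radius: float, thickness: float
) -> np.ndarray:
    r_in = max(radius - thickness, 0.0)
    r3 = rng.uniform(r_in**3, radius**3, size=n)
    return _unit_directions(rng, n) * np.cbrt(r3)[:, None]


def _sample_truncated_gaussian(
    rng: np.random.Generator, n: int, scale: float, radius: float
) -> np.ndarray:
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.normal(scale=scale, size=(2 * (n - filled) + 8, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        take = min(keep.shape[0], n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _sample_centers(
    spec: SyntheticCellSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vesicle offsets from the cell centre (isotropic), plus component labels."""
    n, radius = spec.n_vesicles, spec.cell_radius
    if spec.spatial_model == "uniform_ball":
        return _sample_ball(rng, n, radius), np.full(n, "uniform", dtype=object)
    if spec.spatial_model == "shell":
        return (
            _sample_shell(rng, n, radius, spec.shell_thickness),
            np.full(n, "shell", dtype=object),
        )
    # bimodal: membrane shell with probability membrane_weight, else core.
    # Draw order is fixed (assignment, shell block, core block) so that a
    # change in rendering parameters never perturbs the ground truth.
    on_shell = rng.random(n) < spec.membrane_weight
    offsets = np.empty((n, 3))
    labels = np.where(on_shell, "shell", "core").astype(object)
    n_shell = int(on_shell.sum())
    if n_shell:
        offsets[on_shell] = _sample_shell(rng, n_shell, radius, spec.shell_thickness)
    if n_shell < n:
        offsets[~on_shell] = _sample_truncated_gaussian(
            rng, n - n_shell, spec.core_radius, radius
        )
    return offsets, labels


def generate_cell(spec: SyntheticCellSpec) -> tuple[ImageStack, pd.DataFrame]:
    """Render one synthetic cell; fully deterministic given ``spec.seed``.

    Returns the 16-bit stack and a ground-truth table with one row per
    vesicle: voxel-space centre (z, y, x), spatial component label, and
    rendered peak amplitude above background.
    """
    rng = np.random.default_rng(spec.seed)
    offsets, labels = _sample_centers(spec, rng)
    offsets[:, 0] *= spec.axial_squash
    centers = spec.stack_center + offsets
    j = spec.amplitude_jitter
    amplitudes = spec.amplitude * rng.uniform(1.0 - j, 1.0 + j, size=spec.n_vesicles)

    canvas = np.zeros(spec.shape, dtype=np.float32)
    idx = np.clip(
        np.rint(centers).astype(np.intp),
        0,
        np.asarray(spec.shape, dtype=np.intp) - 1,
    )
    # delta of mass a * (2 pi)^{3/2} sigma^3 blurred by a normalized Gaussian
    # yields a spot of peak height a
    mass = amplitudes * (2.0 * np.pi) ** 1.5 * spec.psf_sigma**3
    np.add.at(canvas, (idx[:, 0], idx[:, 1], idx[:, 2]), mass.astype(np.float32))
    gaussian_filter(canvas, sigma=spec.psf_sigma, mode="constant", output=canvas)

    noise = rng.standard_normal(spec.shape, dtype=np.float32)
    canvas += spec.background_mu + spec.background_sigma * noise
    data = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(
        {
            "z": centers[:, 0],
            "y": centers[:, 1],
            "x": centers[:, 2],
            "component": labels,
            "amplitude": amplitudes,
        }
    )
    stack = ImageStack(data=data, cell_id=spec.cell_id, group=spec.group)
    return stack, truth


def generate_population(
    spec_template: SyntheticCellSpec,
    n_cells: int,
    jitter: float = 0.0,
    group: str | None = None,
    seed: int = 0,
) -> list[tuple[ImageStack, pd.DataFrame]]:
    """Generate a population of cells with per-cell size variation.

    ``cell_radius`` and ``n_vesicles`` are perturbed uniformly within
    ±``jitter`` (relative), emulating natural variation in cell size that
    the R_g scaling is designed to remove. Per-cell seeds derive
    deterministically from ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    if group is None:
        group = spec_template.group
    rng = np.random.default_rng(seed)
    radius_factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=n_cells)
    count_factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=n_cells)
    cell_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    cells = []
    for i in range(n_cells):
        spec = replace(
            spec_template,
            cell_radius=spec_template.cell_radius * radius_factors[i],
            n_vesicles=max(1, int(round(spec_template.n_vesicles * count_factors[i]))),
            seed=int(cell_seeds[i]),
            cell_id=f"{group}_{i:03d}",
            group=group,
        )
        cells.append(generate_cell(spec))
    return cells


def _ellipsoid_mask(
    shape: tuple[int, int, int], radius: float, squash: float
) -> np.ndarray:
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=np.float64) for s in shape), indexing="ij"
    )
    rho = np.sqrt(
        ((zz - center[0]) / squash) ** 2
        + (yy - center[1]) ** 2
        + (xx - center[2]) ** 2
    )
    return rho


def ball_phantom(
    radius: float = 30.0,
    shape: tuple[int, int, int] | None = None,
    squash: float = 1.0,
    value: float = 1000.0,
    cell_id: str = "ball_phantom",
    group: str = "phantom",
) -> ImageStack:
    """Noise-free uniform ball: constant intensity inside, zero outside.

    The deterministic continuum phantom behind the analytic identities
    R_g = sqrt(3/5) R and mean scaled distance (3/4) sqrt(5/3) (isotropic
    case). Thresholding at any theta in (0, value) yields uniform weights
    on the interior voxels.
    """
    if shape is None:
        n = 2 * int(np.ceil(radius)) + 7
        shape = (max(int(np.ceil(2 * radius * squash)) + 7, 8), n, n)
    rho = _ellipsoid_mask(shape, radius, squash)
    data = np.where(rho <= radius, value, 0.0)
    return ImageStack(data=data, cell_id=cell_id, group=group)


def shell_phantom(
    radius: float = 30.0,
    thickness: float = 1.2,
    shape: tuple[int, int, int] | None = None,
    squash: float = 1.0,
    value: float = 1000.0,
    cell_id: str = "shell_phantom",
    group: str = "phantom",
) -> ImageStack:
    """Noise-free thin shell: constant intensity in radius ± thickness/2.

    In the thin limit R_g -> R and all scaled mass concentrates at s = 1.
    """
    if shape is None:
        n = 2 * int(np.ceil(radius + thickness)) + 7
        shape = (max(int(np.ceil(2 * (radius + thickness) * squash)) + 7, 8), n, n)
    rho = _ellipsoid_mask(shape, radius, squash)
    data = np.where(np.abs(rho - radius) <= thickness / 2.0, value, 0.0)
    return ImageStack(data=data, cell_id=cell_id, group=group)
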