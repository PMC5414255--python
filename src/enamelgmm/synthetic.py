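"""Seeded generator of complete synthetic studies.

Emulates the structure of the real study without any downloaded data: a
parametric tooth-outline template (a smoothed ellipse with sinusoidal inward
folds standing in for the flexid lobes of the occlusal enamel pattern), 15
taxon groups x 4 tooth positions with the study's per-group sample sizes,
anatomically coherent mean-shape effects (taxon, tooth position, interaction)
applied as smooth low-frequency displacement fields, Brownian-motion
structured divergence among the 10 tree species, and digitization noise.

Everything is driven by a single integer seed; identical spec + seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Phylogeny, phylo_covariance, phylogeny_from_newick_string
from .scheme import N_CURVES, N_LANDMARKS, SemiLandmarkScheme
from .tps import RawSpecimen, write_tps

#: Per-taxon sample sizes for each tooth position (P3, P4, M1, M2) of the
#: 15-group study design.
TABLE1_SIZES: dict[str, tuple[int, int, int, int]] = {
    "CBL": (15, 15, 15, 15),
    "PRZ": (9, 8, 8, 8),
    "AFR": (7, 7, 7, 7),
    "ASN": (11, 11, 10, 10),
    "KNG": (12, 13, 13, 13),
    "MNG": (13, 10, 13, 13),
    "ONG": (7, 8, 7, 7),
    "KHR": (7, 8, 8, 6),
    "KLN": (9, 12, 10, 11),
    "HMP": (2, 3, 2, 3),
    "GRV": (3, 3, 3, 3),
    "ZBR": (4, 4, 4, 5),
    "QGA": (3, 3, 3, 3),
    "BRC": (8, 8, 8, 8),
    "HBR": (4, 4, 4, 4),
}

TOOTH_ORDER = ("P3", "P4", "M1", "M2")

#: Default 10-species tree: caballine horses sister to the ass/hemione +
#: zebra clades, ultrametric with arbitrary unit-scale branch lengths.
DEFAULT_TREE_NEWICK = (
    "((CBL:1,PRZ:1):3,(((AFR:1,ASN:1):1.5,(ONG:1,KNG:1):1.5):0.5,"
    "((GRV:1.5,ZBR:1.5):0.5,(QGA:1,BRC:1):1):1):1);"
)


@dataclass(frozen=True)
class ToothTemplate:
    """Parametric closed outline: ellipse with sinusoidal inward folds.

    The outline is r(theta) = 1 + amplitude * sin(8 * theta) mapped through
    an ellipse of semi-axes ``axes``; the 8 fixed landmarks sit at the fold
    maxima and the 8 curves run between consecutive landmarks.  For any
    |amplitude| < 1 the radial function stays positive, so the outline never
    self-intersects.
    """

    fold_amplitude: float = 0.12
    axes: tuple[float, float] = (1.6, 1.0)
    points_per_curve: int = 60
    image_scale: float = 100.0    # template units -> image units
    image_offset: tuple[float, float] = (250.0, 250.0)

    def __post_init__(self) -> None:
        if abs(self.fold_amplitude) >= 1.0:
            raise ValueError(
                "fold amplitude must be < 1 (outline would self-intersect)"
            )
        if self.points_per_curve < 2:
            raise ValueError("need at least 2 polyline points per curve")

    # landmark angles: the 8 maxima of sin(8 theta)
    @property
    def landmark_thetas(self) -> np.ndarray:
        return np.pi / 16 + np.arange(N_LANDMARKS) * (2 * np.pi / N_LANDMARKS)

    def outline(self, theta: np.ndarray) -> np.ndarray:
        """(len(theta), 2) points in template units, centered at the origin."""
        r = 1.0 + self.fold_amplitude * np.sin(8 * theta)
        a, b = self.axes
        return np.column_stack([a * r * np.cos(theta), b * r * np.sin(theta)])

    def curve_thetas(self, curve: int) -> np.ndarray:
        t = self.landmark_thetas
        start = t[curve]
        end = t[(curve + 1) % N_LANDMARKS]
        if end <= start:
            end += 2 * np.pi
        return np.linspace(start, end, self.points_per_curve)


# Smooth low-frequency displacement fields used for group mean-shape effects.
# Each field moves outline points radially or tangentially with a slowly
# varying angular profile, mimicking anatomically coherent deformations.
_BASIS_MODES = (
    ("radial", 1, 0.0),
    ("radial", 2, 0.7),
    ("radial", 3, 1.9),
    ("tangential", 1, 0.3),
    ("tangential", 2, 2.1),
)
N_EFFECT_MODES = len(_BASIS_MODES)


def effect_basis(template: ToothTemplate, theta: np.ndarray) -> np.ndarray:
    """(n_modes, len(theta), 2) unit-RMS displacement fields at ``theta``."""
    pts = template.outline(theta)
    radial = pts / np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-12)
    tangential = np.column_stack([-radial[:, 1], radial[:, 0]])
    fields = []
    for kind, freq, phase in _BASIS_MODES:
        profile = np.sin(freq * theta + phase)
        direction = radial if kind == "radial" else tangential
        f = profile[:, None] * direction
        rms = np.sqrt(np.mean(np.sum(f**2, axis=1)))
        fields.append(f / rms)
    return np.asarray(fields)


def make_template(
    scheme: SemiLandmarkScheme | None = None,
    template: ToothTemplate | None = None,
) -> RawSpecimen:
    """One synthetic template 'specimen': 8 landmarks and 8 dense curves."""
    template = template or ToothTemplate()
    return _build_specimen(
        template, coeffs=np.zeros(N_EFFECT_MODES), noise=None,
        specimen_id="template",
    )


def _build_specimen(
    template: ToothTemplate,
    coeffs: np.ndarray,
    noise: tuple[np.random.Generator, float, float] | None,
    specimen_id: str,
) -> RawSpecimen:
    lm_theta = template.landmark_thetas
    curve_theta = [template.curve_thetas(c) for c in range(N_CURVES)]

    def displaced(theta: np.ndarray) -> np.ndarray:
        pts = template.outline(theta)
        basis = effect_basis(template, theta)
        return pts + np.tensordot(coeffs, basis, axes=1)

    lms = displaced(lm_theta)
    curves = [displaced(t) for t in curve_theta]
    if noise is not None:
        rng, noise_sd, jitter = noise
        shift = rng.normal(0.0, noise_sd, size=lms.shape)
        lms = lms + shift
        noisy_curves = []
        for c, th in zip(curves, curve_theta):
            e = rng.normal(0.0, noise_sd, size=(1, 2))  # per-curve coherent noise
            j = rng.normal(0.0, jitter, size=c.shape)   # per-point digitization jitter
            cc = c + e + j
            # keep curve ends anchored at the flanking landmarks
            noisy_curves.append(cc)
        curves = noisy_curves
    s, (ox, oy) = template.image_scale, template.image_offset
    lms = lms * s + (ox, oy)
    curves = [c * s + (ox, oy) for c in curves]
    return RawSpecimen(
        specimen_id=specimen_id, fixed_landmarks=lms, curves=curves, side="left",
    )


def simulate_bm_means(
    phy: Phylogeny,
    template_shape: np.ndarray,
    bm_rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Species mean traits under Brownian motion along the tree.

    Per trait dimension, tip deviations are drawn from a zero-mean Gaussian
    with covariance ``bm_rate * C`` (C the shared-branch-length matrix) and
    added to the template values.  Returns (Y, tip_order) with Y of shape
    (N_tips, d).
    """
    base = np.asarray(template_shape, dtype=float).ravel()
    C, order = phylo_covariance(phy)
    n = len(order)
    rng = np.random.default_rng(seed)
    if bm_rate < 0:
        raise ValueError("bm_rate must be >= 0")
    if bm_rate == 0:
        return np.tile(base, (n, 1)), order
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    dev = np.sqrt(bm_rate) * (L @ rng.standard_normal((n, base.size)))
    return base + dev, order


@dataclass
class SyntheticSpec:
    """Seeded recipe for a complete synthetic study.

    Effect scales are in template units (the template outline has unit
    nominal radius); they control the RMS magnitude of smooth mean-shape
    displacement fields.  ``noise_sd`` is within-group isotropic landmark
    noise and ``digitization_jitter`` extra per-point noise on curve points.
    """

    seed: int = 0
    sample_sizes: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(TABLE1_SIZES)
    )
    scheme: SemiLandmarkScheme = field(default_factory=SemiLandmarkScheme)
    tree_newick: str = DEFAULT_TREE_NEWICK
    template: ToothTemplate = field(default_factory=ToothTemplate)
    bm_rate: float = 1.0
    taxon_effect_scale: float = 0.016
    tooth_effect_scale: float = 0.017
    interaction_scale: float = 0.013
    noise_sd: float = 0.020
    digitization_jitter: float = 0.002
    right_side_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name, val in (
            ("bm_rate", self.bm_rate),
            ("taxon_effect_scale", self.taxon_effect_scale),
            ("tooth_effect_scale", self.tooth_effect_scale),
            ("interaction_scale", self.interaction_scale),
            ("noise_sd", self.noise_sd),
            ("digitization_jitter", self.digitization_jitter),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for taxon, sizes in self.sample_sizes.items():
            if any(s != 0 and s < 2 for s in sizes):
                # 0 means the group is not generated at all
                raise ValueError(
                    f"taxon {taxon}: every generated group needs >= 2 specimens"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.sample_sizes)

    def phylogeny(self) -> Phylogeny:
        return phylogeny_from_newick_string(self.tree_newick)


@dataclass
class SyntheticDataset:
    """Paths and ground truth of one generated study."""

    tps_path: Path
    metadata_path: Path
    newick_path: Path
    taxon_coeffs: dict[str, np.ndarray]
    tooth_coeffs: dict[str, np.ndarray]
    interaction_coeffs: dict[tuple[str, str], np.ndarray]


def generate_dataset(spec: SyntheticSpec, outdir: str | Path) -> SyntheticDataset:
    """Write a full synthetic study (TPS + metadata CSV + newick).

    Specimen shape = template + taxon effect + tooth-position effect +
    interaction effect + noise.  Taxon effects for the 10 tree species are
    Brownian-motion draws on the smooth effect-field coefficients (so species
    divergence carries phylogenetic structure); remaining taxa get
    independent draws of comparable magnitude.  About half the specimens are
    flagged side=right and written mirrored, to exercise the mirroring step.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    phy = spec.phylogeny()
    C, tree_taxa = phylo_covariance(phy)
    mean_depth = float(np.mean(np.diag(C)))

    # taxon effects: BM on effect-mode coefficients for tree species
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tree_taxa)))
    bm = spec.taxon_effect_scale * (
        L @ rng.standard_normal((len(tree_taxa), N_EFFECT_MODES))
    ) / np.sqrt(max(mean_depth, 1e-12))
    taxon_coeffs = {t: bm[i] for i, t in enumerate(tree_taxa)}
    for taxon in spec.taxa:
        if taxon not in taxon_coeffs:
            taxon_coeffs[taxon] = spec.taxon_effect_scale * rng.standard_normal(
                N_EFFECT_MODES
            )
    tooth_coeffs = {
        tooth: spec.tooth_effect_scale * rng.standard_normal(N_EFFECT_MODES)
        for tooth in TOOTH_ORDER
    }
    interaction_coeffs = {
        (taxon, tooth): spec.interaction_scale * rng.standard_normal(N_EFFECT_MODES)
        for taxon in spec.taxa
        for tooth in TOOTH_ORDER
    }

    specimens: list[RawSpecimen] = []
    meta_rows = []
    for taxon in spec.taxa:
        for tooth, n in zip(TOOTH_ORDER, spec.sample_sizes[taxon]):
            for i in range(n):
                coeffs = (
                    taxon_coeffs[taxon]
                    + tooth_coeffs[tooth]
                    + interaction_coeffs[(taxon, tooth)]
                )
                sid = f"{taxon}_{tooth}_{i:02d}"
                s = _build_specimen(
                    spec.template, coeffs,
                    noise=(rng, spec.noise_sd, spec.digitization_jitter),
                    specimen_id=sid,
                )
                side = "right" if rng.random() < spec.right_side_fraction else "left"
                if side == "right":
                    s = _mirror_right(s)
                specimens.append(s)
                meta_rows.append(
                    dict(specimen_id=sid, taxon=taxon, tooth=tooth, side=side)
                )

    tps_path = outdir / "specimens.tps"
    metadata_path = outdir / "metadata.csv"
    newick_path = outdir / "tree.nwk"
    write_tps(tps_path, specimens)
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)
    newick_path.write_text(spec.tree_newick + "\n")
    return SyntheticDataset(
        tps_path=tps_path,
        metadata_path=metadata_path,
        newick_path=newick_path,
        taxon_coeffs=taxon_coeffs,
        tooth_coeffs=tooth_coeffs,
        interaction_coeffs=interaction_coeffs,
    )


def _mirror_right(s: RawSpecimen) -> RawSpecimen:
    """Reflect a generated left-convention specimen into a right-side record."""
    pts = np.vstack([s.fixed_landmarks, *s.curves])
    cx = pts[:, 0].mean()

    def refl(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        q[:, 0] = 2 * cx - q[:, 0]
        return q

    return replace(
        s,
        fixed_landmarks=refl(s.fixed_landmarks),
        curves=[refl(c) for c in s.curves],
        side="right",
    )


def fixture_spec(seed: int = 0) -> SyntheticSpec:
    """A tiny 12-specimen study (3 taxa x 2 tooth positions x 2) for tests."""
    return SyntheticSpec(
        seed=seed,
        sample_sizes={"CBL": (2, 2, 0, 0), "ASN": (2, 2, 0, 0), "GRV": (2, 2, 0, 0)},
        template=ToothTemplate(points_per_curve=50),
    )


def fixture_dataset(outdir: str | Path, seed: int = 0) -> SyntheticDataset:
    """Generate the tiny 12-specimen fixture study into ``outdir``."""
    return generate_dataset(fixture_spec(seed), outdir)
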