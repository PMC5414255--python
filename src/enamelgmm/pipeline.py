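"""End-to-end orchestration of the enamel-shape analyses.

Mirrors the study workflow: read digitizations + metadata, mirror right
sides, resample curves to semi-landmarks, superimpose (jointly across the
four tooth positions for the factorial analysis, and per tooth for the
taxonomic analyses), then run the discriminant, factorial-ANOVA and
phylogenetic-signal layers, writing machine-readable tables.

Analysis constants default to the study's values: 99% PCA retention, 10 000
cross-validation rounds, 999 ANOVA permutations, 1000 K permutations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .phylo import kmult, phylomorphospace, read_newick, species_mean_shapes
from .procrustes import AlignedSample, gpa, resample_curves
from .scheme import DEFAULT_COUNTS, SemiLandmarkScheme
from .stats import (
    crossvalidated_classification,
    factorial_shape_anova,
    manova_pillai,
    pca,
)
from .tps import TOOTH_POSITIONS, mirror_to_left, read_metadata, read_tps

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and analysis constants for one pipeline run."""

    tps_path: Path
    metadata_path: Path
    outdir: Path
    newick_path: Path | None = None
    counts_per_curve: tuple[int, ...] = DEFAULT_COUNTS
    pca_threshold: float = 0.99
    cv_rounds: int = 10_000
    anova_n_perm: int = 999
    kmult_n_perm: int = 1000
    seed: int = 0
    slide: bool = True
    skip_resample: bool = False
    plot: bool = False                # write phylomorphospace SVGs
    bulk_outdir: Path | None = None   # large outputs (aligned tables,
                                      # permutation dumps); defaults to outdir

    def __post_init__(self) -> None:
        self.tps_path = Path(self.tps_path)
        self.metadata_path = Path(self.metadata_path)
        self.outdir = Path(self.outdir)
        self.bulk_outdir = Path(self.bulk_outdir or self.outdir)
        if self.newick_path is not None:
            self.newick_path = Path(self.newick_path)
        for p in (self.tps_path, self.metadata_path):
            if not p.exists():
                raise FileNotFoundError(p)
        if self.newick_path is not None and not self.newick_path.exists():
            raise FileNotFoundError(self.newick_path)

    @property
    def scheme(self) -> SemiLandmarkScheme:
        return SemiLandmarkScheme(tuple(self.counts_per_curve))


def load_configurations(config: RunConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Read TPS + metadata, mirror right sides, resample curves.

    Returns (n, p, 2) configurations and the per-specimen metadata in the
    same order.
    """
    meta = read_metadata(config.metadata_path)
    specimens = read_tps(config.tps_path, metadata=meta)
    scheme = config.scheme
    configs = []
    rows = []
    for s in specimens:
        if s.side == "right":
            s = mirror_to_left(s)
        if config.skip_resample:
            counts = tuple(len(c) for c in s.curves)
            if counts != tuple(scheme.counts_per_curve):
                raise ValueError(
                    f"{s.specimen_id}: skip_resample set but curve point counts "
                    f"{counts} do not match the scheme {scheme.counts_per_curve}"
                )
            cfg = np.vstack([s.fixed_landmarks, *s.curves])
        else:
            cfg = resample_curves(s, scheme)
        configs.append(cfg)
        rows.append(
            dict(specimen_id=s.specimen_id, taxon=s.taxon_code, tooth=s.tooth_position)
        )
    arr = np.asarray(configs)
    out_meta = pd.DataFrame(rows)
    if arr.shape[0] != len(out_meta):
        raise AssertionError("specimen bookkeeping mismatch")
    return arr, out_meta


def aligned_table(sample: AlignedSample, meta: pd.DataFrame) -> pd.DataFrame:
    """One row per specimen: id, taxon, tooth, centroid size, coordinates."""
    p = sample.n_points
    cols = [f"{ax}{i+1}" for i in range(p) for ax in ("x", "y")]
    df = pd.DataFrame(sample.coords, columns=cols)
    out = pd.concat(
        [
            meta[["specimen_id", "taxon", "tooth"]].reset_index(drop=True),
            pd.Series(sample.centroid_sizes, name="centroid_size"),
            df,
        ],
        axis=1,
    )
    return out


def read_aligned_table(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read an aligned-coordinates table back into (X, metadata)."""
    df = pd.read_csv(path)
    meta_cols = ["specimen_id", "taxon", "tooth", "centroid_size"]
    X = df.drop(columns=meta_cols).to_numpy(dtype=float)
    return X, df[meta_cols]


def cmd_align(config: RunConfig) -> dict[str, tuple[AlignedSample, pd.DataFrame]]:
    """Superimpose per tooth position and jointly; write coordinate tables.

    The joint superimposition (all four teeth together) feeds the factorial
    and anatomical analyses; the per-tooth superimpositions feed the
    taxonomic and phylogenetic analyses.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    config.bulk_outdir.mkdir(parents=True, exist_ok=True)
    arr, meta = load_configurations(config)
    scheme = config.scheme
    results: dict[str, tuple[AlignedSample, pd.DataFrame]] = {}

    def _run(subset: np.ndarray, sub_meta: pd.DataFrame, tag: str) -> None:
        sample = gpa(list(subset), scheme=scheme, slide=config.slide)
        if not sample.converged:
            log.warning("GPA for %s did not fully converge", tag)
        results[tag] = (sample, sub_meta.reset_index(drop=True))
        aligned_table(sample, sub_meta).to_csv(
            config.bulk_outdir / f"aligned_{tag}.csv", index=False
        )

    _run(arr, meta, "joint")
    for tooth in TOOTH_POSITIONS:
        mask = (meta["tooth"] == tooth).to_numpy()
        if mask.sum() >= 2:
            _run(arr[mask], meta[mask], tooth)
    n_out = sum(len(m) for t, (s, m) in results.items() if t != "joint")
    if n_out != len(meta):
        log.warning("per-tooth outputs cover %d of %d specimens", n_out, len(meta))
    return results


def _capped_retained_scores(
    X: np.ndarray, groups: np.ndarray, threshold: float
) -> np.ndarray:
    """Retained-PC scores, capped so twofold CVA training stays full rank."""
    model = pca(X, threshold=threshold)
    g = len(np.unique(groups))
    cap = max(1, len(groups) // 2 - g - 1)
    m = min(model.retained_m, cap)
    if m < model.retained_m:
        log.info(
            "capping retained PCs at %d (was %d) for cross-validation rank", m,
            model.retained_m,
        )
    return model.scores[:, :m]


def cmd_classify(
    config: RunConfig,
    aligned: dict[str, tuple[AlignedSample, pd.DataFrame]] | None = None,
) -> pd.DataFrame:
    """Per-tooth taxonomic MANOVA + cross-validated classification.

    Writes a table with Pillai's trace, its approximate F and dfs, and the
    CCV percentage for each tooth position, plus per-tooth confusion
    matrices.
    """
    aligned = aligned or cmd_align(config)
    rows = []
    for tooth in TOOTH_POSITIONS:
        if tooth not in aligned:
            continue
        sample, meta = aligned[tooth]
        groups = meta["taxon"].to_numpy()
        scores = _capped_retained_scores(
            sample.coords, groups, config.pca_threshold
        )
        man = manova_pillai(scores, groups)
        report = crossvalidated_classification(
            scores, groups, rounds=config.cv_rounds, seed=config.seed,
            ids=list(meta["specimen_id"]),
        )
        report.confusion.to_csv(config.outdir / f"confusion_taxa_{tooth}.csv")
        rows.append(
            dict(
                tooth=tooth, Pillai=man.pillai, approx_F=man.approx_f,
                num_df=man.num_df, den_df=man.den_df, p=man.p,
                CCV=report.ccv, CCV_modal=report.ccv_modal,
            )
        )
    table = pd.DataFrame(rows)
    table.to_csv(config.outdir / "taxonomic_classification.csv", index=False)
    return table


def cmd_anatomy(
    config: RunConfig,
    aligned: dict[str, tuple[AlignedSample, pd.DataFrame]] | None = None,
) -> dict:
    """Four-class (tooth position) CVA with cross-validated classification."""
    aligned = aligned or cmd_align(config)
    sample, meta = aligned["joint"]
    groups = meta["tooth"].to_numpy()
    scores = _capped_retained_scores(sample.coords, groups, config.pca_threshold)
    report = crossvalidated_classification(
        scores, groups, rounds=config.cv_rounds, seed=config.seed,
        ids=list(meta["specimen_id"]),
    )
    report.confusion.to_csv(config.outdir / "confusion_anatomy.csv")
    out = dict(ccv=report.ccv, ccv_modal=report.ccv_modal,
               ccv_per_group=report.ccv_per_group)
    (config.outdir / "anatomy_classification.json").write_text(
        json.dumps(out, indent=2)
    )
    return out


def cmd_anova(
    config: RunConfig,
    aligned: dict[str, tuple[AlignedSample, pd.DataFrame]] | None = None,
) -> pd.DataFrame:
    """Factorial shape-ANOVA (anatomical position, taxa, interaction)."""
    aligned = aligned or cmd_align(config)
    sample, meta = aligned["joint"]
    table = factorial_shape_anova(
        sample.coords,
        meta["tooth"], meta["taxon"],
        n_perm=config.anova_n_perm, seed=config.seed,
        term_names=("anatomical position", "taxa", "anatomical position : taxa"),
    )
    table.table.to_csv(config.outdir / "factorial_anova.csv")
    return table.table


def cmd_physignal(
    config: RunConfig,
    aligned: dict[str, tuple[AlignedSample, pd.DataFrame]] | None = None,
) -> pd.DataFrame:
    """Per-tooth phylogenetic signal (K) and phylomorphospace coordinates."""
    if config.newick_path is None:
        raise ValueError("physignal requires a newick tree (newick_path)")
    aligned = aligned or cmd_align(config)
    phy = read_newick(config.newick_path)
    rows = []
    for tooth in TOOTH_POSITIONS:
        if tooth not in aligned:
            continue
        sample, meta = aligned[tooth]
        labels = meta["taxon"].to_numpy()
        keep = np.isin(labels, phy.tip_labels)
        if keep.sum() < 3:
            log.warning("%s: too few tree species with data; skipped", tooth)
            continue
        means, species = species_mean_shapes(sample.shapes[keep], labels[keep])
        sub_phy = phy.pruned_to(species) if set(species) != set(phy.tip_labels) else phy
        res = kmult(
            means, sub_phy, species, n_perm=config.kmult_n_perm, seed=config.seed
        )
        pms = phylomorphospace(
            means, species, sub_phy, threshold=config.pca_threshold
        )
        coord_rows = []
        for s in species:
            c = pms.tip_coords[s]
            coord_rows.append(dict(node=s, kind="tip", PC1=c[0],
                                   PC2=c[1] if len(c) > 1 else 0.0))
        for nid, c in pms.node_coords.items():
            coord_rows.append(dict(node=nid, kind="internal", PC1=c[0],
                                   PC2=c[1] if len(c) > 1 else 0.0))
        pd.DataFrame(coord_rows).to_csv(
            config.outdir / f"phylomorphospace_{tooth}.csv", index=False
        )
        pd.DataFrame(pms.edges, columns=["parent", "child"]).to_csv(
            config.outdir / f"phylomorphospace_edges_{tooth}.csv", index=False
        )
        if config.plot:
            from .plot import plot_phylomorphospace

            plot_phylomorphospace(
                pms, config.bulk_outdir / f"phylomorphospace_{tooth}.svg",
                title=f"{tooth} phylomorphospace",
            )
        np.savetxt(
            config.bulk_outdir / f"kmult_permutations_{tooth}.csv",
            res.permutation_distribution, delimiter=",",
        )
        rows.append(dict(tooth=tooth, Kmult_obs=res.k_obs, p_value=res.p_perm,
                         n_perm=res.n_perm))
    table = pd.DataFrame(rows)
    table.to_csv(config.outdir / "phylogenetic_signal.csv", index=False)
    return table


def cmd_all(config: RunConfig) -> dict:
    """Full seeded run; writes every table plus a JSON run report."""
    t0 = time.time()
    aligned = cmd_align(config)
    classify = cmd_classify(config, aligned)
    anatomy = cmd_anatomy(config, aligned)
    anova = cmd_anova(config, aligned)
    physig = (
        cmd_physignal(config, aligned).to_dict(orient="records")
        if config.newick_path is not None
        else None
    )
    n_in = sum(len(m) for t, (s, m) in aligned.items() if t == "joint")
    report = dict(
        version=__version__,
        seed=config.seed,
        n_specimens=int(n_in),
        pca_threshold=config.pca_threshold,
        cv_rounds=config.cv_rounds,
        anova_n_perm=config.anova_n_perm,
        kmult_n_perm=config.kmult_n_perm,
        slide=config.slide,
        taxonomic=classify.to_dict(orient="records"),
        anatomy=anatomy,
        factorial_anova=anova.reset_index().to_dict(orient="records"),
        phylogenetic_signal=physig,
        elapsed_seconds=round(time.time() - t0, 2),
    )
    (config.outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
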