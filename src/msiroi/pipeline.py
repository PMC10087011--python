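"""Stage orchestration: each stage reads its inputs from a run directory,
writes its artifacts back there, and can therefore be executed either in one
go (:func:`run_pipeline`) or stage by stage from the CLI.

Artifact layout inside the run directory::

    config.json          resolved configuration
    msi_cube.h5          preprocessed MSI cube (native grid)
    hf_cube.h5           HF cube on the tile grid
    he_image.png         rendered / copied H&E image (phantom or input)
    msi_warped.h5        MSI cube resampled onto the HF grid
    transform.tfm        fitted spatial transform (ITK format)
    registration_qc.json mask-overlap QC
    labels_<mod>.csv     long-format labelings (K, row, col, label)
    cks_curve.csv/.png   consistency curve and criteria plot
    criteria.csv         PC / DBI baselines (when enabled)
    roi_regions.csv      confident-pixel lists per region
    ion_ranking.csv      characteristic-ion ranking
    roi_map.png          confidence-masked label rendering
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import dataio, histofeat, preprocess, registration, roi as roimod
from .config import RunConfig
from .cubes import HFCube, MSICube
from .errors import ConfigError
from .phantom import Phantom, PhantomParams, generate_phantom
from .segmentation import Labeling, SegmentParams, sweep_k
from .validation import (ConsistencyCurve, cks_curve_select, dbi_criterion,
                         pc_criterion)

log = logging.getLogger("msiroi")

__all__ = ["run_pipeline", "stage_preprocess", "stage_features",
           "stage_register", "stage_segment", "stage_select_k", "stage_rois"]


def _phantom_for(cfg: RunConfig) -> Phantom:
    p = cfg.phantom
    params = PhantomParams(
        K_true=p.K_true, grid_shape=(p.grid_rows, p.grid_cols),
        n_channels_msi=p.n_channels_msi, n_features_hf=p.n_features_hf,
        msi_noise=p.msi_noise, hf_noise=p.hf_noise,
        saltpepper_rate=p.saltpepper_rate, deformation_px=p.deformation_px,
        translation_px=(p.translation_y, p.translation_x),
        spurious_region=p.spurious_region)
    return generate_phantom(params, seed=cfg.stage_seed("phantom"))


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise ConfigError(f"missing intermediate {path.name}; run the "
                          f"'{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_preprocess(cfg: RunConfig) -> MSICube:
    """Produce the preprocessed MSI cube (phantom or imzML input)."""
    out = _outdir(cfg)
    if cfg.phantom.enabled:
        ph = _phantom_for(cfg)
        cube = ph.msi
        Image.fromarray(ph.he_image).save(out / "he_image.png")
    else:
        pc = cfg.preprocess
        if pc.imzml_path is None or not Path(pc.imzml_path).exists():
            raise ConfigError(
                f"preprocess.imzml_path {pc.imzml_path!r} does not exist")
        cube = dataio.read_imzml(pc.imzml_path, pc.pixel_size_um)
        cube = preprocess.tic_normalize(cube)
        cube = preprocess.peak_pipeline(cube, preprocess.PreprocessParams(
            smoothing_window=pc.smoothing_window, snr=pc.snr,
            alignment_tol=pc.alignment_tol,
            min_pixel_freq=pc.min_pixel_freq, centroided=pc.centroided))
        ions = pc.tissue_ions
        if ions is None:
            # bootstrap: provisional noisy-ion drop defines the tissue ions
            provisional = preprocess.drop_noisy_ions(cube)
            ions = provisional.mz_axis.tolist()
        cube.foreground_mask = preprocess.msi_foreground(
            cube, ions, pc.foreground_threshold)
        cube = preprocess.drop_noisy_ions(cube)
    dataio.write_cube(cube, out / "msi_cube.h5")
    return cube


def stage_features(cfg: RunConfig) -> HFCube:
    """Produce the HF cube from the H&E image (or phantom prototypes)."""
    out = _outdir(cfg)
    if cfg.phantom.enabled and not cfg.histo.from_image:
        cube = _phantom_for(cfg).hf
    else:
        hc = cfg.histo
        if cfg.phantom.enabled:
            image = np.asarray(Image.open(
                _require(out / "he_image.png", "preprocess")))
            he_um, msi_um = 1.0, float(_phantom_for(cfg).hf.tile_size_px)
        else:
            if hc.wsi_path is None:
                raise ConfigError("histo.wsi_path is not set")
            image, _ = dataio.read_wsi(hc.wsi_path, hc.he_pixel_um)
            he_um = hc.he_pixel_um
            msi_cube = dataio.read_cube(
                _require(out / "msi_cube.h5", "preprocess"))
            msi_um = msi_cube.pixel_size_um
        mask, image = histofeat.prepare_wsi(image)
        grid, tiles = histofeat.tile_image(image, he_um, msi_um, mask)
        fg = histofeat.tile_foreground(grid, hc.min_tissue_fraction)
        vectors = histofeat.extract_hf(tiles[fg], backend=hc.backend,
                                       weights=hc.weights,
                                       seed=cfg.stage_seed("histofeat"))
        cube = histofeat.scale_features(vectors, grid,
                                        {"backend": hc.backend})
    dataio.write_cube(cube, out / "hf_cube.h5")
    return cube


def stage_register(cfg: RunConfig) -> MSICube:
    """Fit the MSI->HF transform and warp every ion channel."""
    out = _outdir(cfg)
    msi = dataio.read_cube(_require(out / "msi_cube.h5", "preprocess"))
    hf = dataio.read_cube(_require(out / "hf_cube.h5", "features"))
    rc = cfg.registration
    if not rc.enabled:
        dataio.write_cube(msi, out / "msi_warped.h5")
        return msi
    seed = cfg.stage_seed("register")
    msi_maps = registration.nmf_scoremaps(msi, rc.rank, seed)
    hf_maps = registration.nmf_scoremaps(hf, rc.rank, seed)
    fixed, moving = registration.select_pair(
        msi_maps, hf_maps, rc.pair_mode, rc.manual_pair,
        rc.correlation_floor)
    params = registration.RegistrationParams(
        mi_bins=rc.mi_bins,
        bspline_control_spacing_px=rc.bspline_control_spacing_px)
    tr = registration.register_maps(fixed, moving, params)
    tr.save(str(out / "transform.tfm"))
    warped = registration.warp_cube(msi, tr, hf.grid_shape)
    qc = registration.registration_qc(hf.foreground_mask,
                                      warped.foreground_mask)
    Image.fromarray(qc.pop("overlay")).save(out / "registration_qc.png")
    (out / "registration_qc.json").write_text(json.dumps(
        {**qc, "metric_initial": tr.metric_initial,
         "metric_final": tr.metric_final,
         "fixed_component": fixed.component,
         "moving_component": moving.component}, indent=2))
    dataio.write_cube(warped, out / "msi_warped.h5")
    return warped


def _labelings_to_csv(labelings: list[Labeling], path: Path) -> None:
    frames = []
    for lab in labelings:
        df = lab.to_frame()
        df.insert(0, "K", lab.K)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def _labelings_from_csv(path: Path, grid_shape: tuple[int, int],
                        modality: str, seed: int) -> list[Labeling]:
    df = pd.read_csv(path)
    out = []
    for K, sub in df.groupby("K"):
        mask = np.zeros(grid_shape, dtype=bool)
        mask[sub["row"], sub["col"]] = True
        lmap = np.zeros(grid_shape, dtype=int)
        lmap[sub["row"], sub["col"]] = sub["label"]
        out.append(Labeling(lmap[mask], int(K), modality, seed, mask))
    return out


def stage_segment(cfg: RunConfig) -> tuple[list[Labeling], list[Labeling]]:
    """Sweep K for both modalities on the shared grid."""
    out = _outdir(cfg)
    msi = dataio.read_cube(_require(out / "msi_warped.h5", "register"))
    hf = dataio.read_cube(_require(out / "hf_cube.h5", "features"))
    sc = cfg.segment
    params = SegmentParams(n_pca=sc.n_pca, n_neighbors=sc.n_neighbors)
    krange = range(sc.k_min, sc.k_max + 1)
    msi_l = sweep_k(msi, krange, cfg.stage_seed("segment-msi"), params)
    hf_l = sweep_k(hf, krange, cfg.stage_seed("segment-hf"), params)
    _labelings_to_csv(msi_l, out / "labels_msi.csv")
    _labelings_to_csv(hf_l, out / "labels_hf.csv")
    return msi_l, hf_l


def stage_select_k(cfg: RunConfig) -> ConsistencyCurve:
    """CKS curve (and PC/DBI baselines) -> K*."""
    out = _outdir(cfg)
    msi = dataio.read_cube(_require(out / "msi_warped.h5", "register"))
    hf = dataio.read_cube(_require(out / "hf_cube.h5", "features"))
    seed = cfg.stage_seed("segment-msi")
    msi_l = _labelings_from_csv(_require(out / "labels_msi.csv", "segment"),
                                msi.grid_shape, "msi", seed)
    hf_l = _labelings_from_csv(_require(out / "labels_hf.csv", "segment"),
                               hf.grid_shape, "hf",
                               cfg.stage_seed("segment-hf"))
    curve = cks_curve_select(msi_l, hf_l)
    curve.to_frame().to_csv(out / "cks_curve.csv", index=False)

    crit_frames = {}
    vc = cfg.validation
    params = SegmentParams(n_pca=cfg.segment.n_pca,
                           n_neighbors=cfg.segment.n_neighbors)
    if vc.pc:
        pc = pc_criterion(msi, msi_l, runs=vc.pc_runs,
                          seed=cfg.stage_seed("pc"), params=params,
                          embed_method=vc.embed_method)
        crit_frames["pc_mean"] = pc.values
        crit_frames["pc_std"] = pc.dispersion
    if vc.dbi:
        dbi = dbi_criterion(msi, msi_l, params=params)
        crit_frames["dbi"] = dbi.values
    if crit_frames:
        pd.DataFrame({"K": curve.ks, **crit_frames}).to_csv(
            out / "criteria.csv", index=False)
    _plot_curves(out, curve, crit_frames)
    return curve


def _plot_curves(out: Path, curve: ConsistencyCurve,
                 crit: dict[str, list[float]]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.ks, curve.kappas, "g-o", label="CKS")
    if "pc_mean" in crit:
        ax.errorbar(curve.ks, crit["pc_mean"], yerr=crit.get("pc_std"),
                    fmt="r--s", label="PC")
    if "dbi" in crit:
        ax2 = ax.twinx()
        ax2.plot(curve.ks, crit["dbi"], "b:^", label="DBI")
        ax2.set_ylabel("DBI")
    ax.axvline(curve.best_k, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("#Clusters")
    ax.set_ylabel("CKS / PC")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "cks_curve.png", dpi=150)
    plt.close(fig)


def stage_rois(cfg: RunConfig) -> roimod.ROISet:
    """Fuse the two labelings at K*, rank ions, render overlays."""
    from .validation import align_labels

    out = _outdir(cfg)
    msi = dataio.read_cube(_require(out / "msi_warped.h5", "register"))
    curve = pd.read_csv(_require(out / "cks_curve.csv", "select-k"))
    best_k = int(curve.loc[curve["kappa"].idxmax(), "K"])
    msi_l = _labelings_from_csv(_require(out / "labels_msi.csv", "segment"),
                                msi.grid_shape, "msi",
                                cfg.stage_seed("segment-msi"))
    hf_l = _labelings_from_csv(_require(out / "labels_hf.csv", "segment"),
                               msi.grid_shape, "hf",
                               cfg.stage_seed("segment-hf"))
    m = next(l for l in msi_l if l.K == best_k)
    h = next(l for l in hf_l if l.K == best_k)
    perm, _ = align_labels(m, h)
    roiset = roimod.integrate_labels(m, h, perm)
    roiset.meta["msi_label_map"] = m.label_map()

    regions = roimod.extract_rois(roiset)
    rows = [(rid, info["n_pixels"], info["confident_fraction"])
            for rid, info in regions.items()]
    pd.DataFrame(rows, columns=["region", "n_pixels", "confident_fraction"]
                 ).to_csv(out / "roi_regions.csv", index=False)
    ranking = roimod.rank_ions(msi, roiset, cfg.roi.top_n_ions)
    ranking.to_frame().to_csv(out / "ion_ranking.csv", index=False)
    rgb = roimod.render_label_rgb(roiset, alpha=cfg.roi.unconfident_alpha)
    Image.fromarray(rgb).save(out / "roi_map.png")
    he_path = out / "he_image.png"
    if he_path.exists():
        he = np.asarray(Image.open(he_path))
        factor = he.shape[0] // roiset.grid_shape[0]
        if factor >= 1:
            overlay = roimod.render_overlay(rgb, he, factor,
                                            alpha=cfg.roi.unconfident_alpha,
                                            is_label_map=True)
            Image.fromarray(overlay).save(out / "roi_overlay.png")
    return roiset


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage in order; rerunning with the same config and
    seed reproduces all numeric outputs."""
    out = _outdir(cfg)
    cfg.dump(out / "config.json")
    t0 = time.time()
    for name, fn in [("preprocess", stage_preprocess),
                     ("features", stage_features),
                     ("register", stage_register),
                     ("segment", stage_segment),
                     ("select-k", stage_select_k),
                     ("rois", stage_rois)]:
        t = time.time()
        try:
            fn(cfg)
        except Exception:
            log.exception("stage %s failed; partial outputs kept in %s",
                          name, out)
            raise
        log.info("stage %-10s %6.1fs", name, time.time() - t)
    log.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out
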