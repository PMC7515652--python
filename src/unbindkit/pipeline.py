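"""End-to-end orchestration on the built-in toy landscapes.

``run_pipeline`` chains the stages the way the full protocol runs against
an MD engine: a short unbiased run with feature tracking, mutual-information
feature selection, a first learned reaction coordinate (RC), a well-tempered
metadynamics run biased along that RC, RC retraining on the reweighted
biased data, a batch of infrequent-metadynamics unbinding runs, Bayesian
residence-time inference with KS validation, landscape/pathway analysis and
a state-conditioned contact report.  Every stage writes its artifacts and a
parameter manifest into the run directory and draws its randomness from a
stage-keyed seed, so a run is fully reproducible from (config, seed).

``fixture_generator`` materialises small deterministic input bundles
(COLVAR/CSV) for the packaged toy scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import collective_variables as cvmod
from . import feature_select, kinetics, landscape, rc_learner
from .config import PipelineConfig, get_logger, stage_seed
from .io import TimeSeriesTable, write_colvar, write_csv_table, write_hills
from .toy_dynamics import (
    LinearCV,
    MetadParams,
    MixtureSurface,
    UnbindingCriterion,
    run_langevin,
    run_metadynamics,
    run_unbinding,
)

__all__ = ["ToyScenario", "make_scenario", "run_pipeline", "fixture_generator"]


# ======================================================================
# Toy scenarios
# ======================================================================

@dataclass
class ToyScenario:
    """A packaged study system: landscape, feature map and unbinding rule."""

    name: str
    surface: MixtureSurface
    x0: np.ndarray                  # bound-state start
    feature_map: np.ndarray         # (n_features, D) linear feature channels
    feature_noise: float
    feature_names: list[str]
    unbind_axis: int                # position coordinate defining dissociation
    unbind_threshold: float
    cv_grid: tuple[tuple[float, float], ...]  # per-CV (lo, hi) bias-grid range
    contact_sites: np.ndarray       # reference points for synthetic distances


def _block_feature_map(signals: np.ndarray, copies: int, rng) -> tuple[np.ndarray, list[str]]:
    """Each signal row is duplicated ``copies`` times with scale jitter."""
    rows = []
    names = []
    for b, s in enumerate(signals):
        for c in range(copies):
            rows.append(s * (0.8 + 0.4 * rng.random()))
            names.append(f"d{b+1}{c+1}")
    return np.asarray(rows), names


def make_scenario(name: str, seed: int = 0) -> ToyScenario:
    """Build one of the packaged toy scenarios (deterministic per seed)."""
    rng = np.random.default_rng(stage_seed(seed, "toy"))
    if name in ("double-well-1d", "double-well-1D"):
        surface = MixtureSurface.double_well_1d(separation=2.0, sigma=0.24, beta=1.0)
        fmap, names = _block_feature_map(np.array([[1.0]]), 3, rng)
        return ToyScenario(
            name="double-well-1d",
            surface=surface,
            x0=np.array([-1.0]),
            feature_map=fmap,
            feature_noise=0.15,
            feature_names=names,
            unbind_axis=0,
            unbind_threshold=1.4,
            cv_grid=((-2.5, 2.5),),
            contact_sites=np.array([[-1.0], [0.0], [1.0]]),
        )
    if name in ("three-state-2d", "three-state-2D"):
        # bound ground state (OS), metastable vestibule (VRS), dissociated (DS)
        surface = MixtureSurface(
            [
                (0.55, [0.0, 0.0], np.eye(2) * 0.08),
                (0.35, [1.4, 0.6], np.eye(2) * 0.10),
                (0.10, [2.8, 0.0], np.eye(2) * 0.35),
            ],
            beta=1.0,
        )
        signals = np.array([[1.0, 0.0], [0.0, 1.0], [0.7, 0.7]])
        fmap, names = _block_feature_map(signals, 3, rng)
        return ToyScenario(
            name="three-state-2d",
            surface=surface,
            x0=np.array([0.0, 0.0]),
            feature_map=fmap,
            feature_noise=0.15,
            feature_names=names,
            unbind_axis=0,
            unbind_threshold=2.4,
            cv_grid=((-2.0, 5.0), (-2.0, 5.0)),
            contact_sites=np.array([[0.0, 0.0], [1.4, 0.6], [2.8, 0.0], [0.0, 1.5]]),
        )
    raise KeyError(f"unknown scenario '{name}'")


def _feature_table(scenario: ToyScenario, traj, rng) -> TimeSeriesTable:
    """Synthetic feature channels: linear projections of position plus noise."""
    pos = traj.positions()
    f = pos @ scenario.feature_map.T
    f += scenario.feature_noise * rng.standard_normal(f.shape)
    cols = {n: f[:, i] for i, n in enumerate(scenario.feature_names)}
    cols["bias"] = traj.bias_at_frame
    return TimeSeriesTable.from_arrays(traj.table.times, cols, meta=dict(traj.table.meta))


def _rc_position_cv(model: rc_learner.RCModel, scenario: ToyScenario) -> np.ndarray:
    """Fold the learned feature-space RC back onto position space.

    Toy features are linear in position, so z = w . ((M x + eps) - mu)/sd is
    itself linear in x up to noise; the effective biasing direction is
    M^T (w / sd), normalised.
    """
    w_eff = model.w / (model.feature_std if model.feature_std is not None else 1.0)
    rows = [scenario.feature_names.index(n) for n in model.feature_names]
    a = scenario.feature_map[rows].T @ w_eff
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("degenerate reaction coordinate")
    return a / n


# ======================================================================
# Pipeline
# ======================================================================

def _write_manifest(out: Path, stage: str, payload: dict) -> None:
    (out / f"{stage}.manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full toy protocol; returns the summary dict.

    Artifacts and per-stage manifests are written under ``out_dir``; the
    summary is also stored as ``summary.json``.  Fully reproducible from
    (config, config.seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = get_logger("pipeline")
    scenario = make_scenario(config.toy.scenario, config.seed)
    surface = scenario.surface
    beta = config.toy.beta
    summary: dict = {"scenario": scenario.name, "seed": config.seed}

    # -- 1. unbiased run with feature tracking -------------------------
    log.info("stage 1: unbiased run")
    traj0 = run_langevin(
        surface, config.toy.step, config.toy.unbiased_steps,
        friction=config.toy.friction, seed=stage_seed(config.seed, "unbiased"),
        x0=scenario.x0, stride=config.toy.stride,
    )
    feat_rng = np.random.default_rng(stage_seed(config.seed, "features"))
    table0 = _feature_table(scenario, traj0, feat_rng)
    write_colvar(table0, out / "unbiased_features.colvar")
    _write_manifest(out, "unbiased", {
        "seed": stage_seed(config.seed, "unbiased"), "n_steps": config.toy.unbiased_steps,
        "step": config.toy.step, "inputs": [], "outputs": ["unbiased_features.colvar"],
    })

    # -- 2. feature selection ------------------------------------------
    log.info("stage 2: mutual-information feature selection")
    fm = feature_select.FeatureMatrix(
        table0.values(scenario.feature_names), scenario.feature_names,
        frame_times=table0.times,
    )
    clustering = feature_select.cluster_features(
        fm, max_clusters=config.features.max_clusters, n_bins=config.features.n_bins
    )
    reps = clustering.representatives
    (out / "clusters.json").write_text(json.dumps(clustering.to_dict(), indent=2))
    summary["n_feature_clusters"] = clustering.n_clusters
    summary["representatives"] = reps

    # -- 3. RC round 1 on unbiased data --------------------------------
    log.info("stage 3: RC training round 1")
    rc1, rec1 = rc_learner.train_rc(
        table0, lag=config.rc.lag, epochs=config.rc.epochs, lr=config.rc.lr,
        K=config.rc.hidden, seed=stage_seed(config.seed, "rc_round1"),
        feature_columns=reps, beta=beta,
    )
    rc1.save(out / "rc1.h5")
    summary["rc1_coefficients"] = rc1.reported_coefficients().tolist()
    summary["rc1_fractional_loss"] = float(rec1.fractional_loss[-1])

    # -- 4. metadynamics along RC1 -------------------------------------
    log.info("stage 4: metadynamics along RC1")
    a1 = _rc_position_cv(rc1, scenario)
    cv1 = LinearCV(a1[None, :], names=["rc"])
    lo, hi = scenario.cv_grid[0]
    mparams = MetadParams(
        hill_height=config.metad.hill_height, hill_width=config.metad.hill_width,
        bias_factor=config.metad.bias_factor,
        deposition_interval=config.metad.deposition_interval,
        grid_min=(lo,), grid_max=(hi,),
    )
    traj1 = run_metadynamics(
        surface, cv1, mparams, config.toy.step, config.metad.n_steps,
        seed=stage_seed(config.seed, "metad"), friction=config.toy.friction,
        x0=scenario.x0, stride=config.metad.stride,
    )
    table1 = _feature_table(scenario, traj1, feat_rng)
    write_colvar(table1, out / "metad_features.colvar")
    write_hills(traj1.hill_log, cv1.names, out / "metad.hills")

    # -- 5. RC round 2 with bias reweighting ---------------------------
    log.info("stage 5: RC retraining on biased data")
    rc2, rec2 = rc_learner.train_rc(
        table1, lag=config.rc.lag, epochs=config.rc.epochs, lr=config.rc.lr,
        K=config.rc.hidden, seed=stage_seed(config.seed, "rc_round2"),
        feature_columns=reps, beta=beta,
    )
    rc2.save(out / "rc2.h5")
    summary["rc2_coefficients"] = rc2.reported_coefficients().tolist()
    summary["rc2_fractional_loss"] = float(rec2.fractional_loss[-1])
    summary["rc1_direction"] = _rc_position_cv(rc1, scenario).tolist()
    summary["rc2_direction"] = _rc_position_cv(rc2, scenario).tolist()

    # -- 6. infrequent-metadynamics unbinding batch --------------------
    log.info("stage 6: %d infrequent unbinding runs", config.unbind.n_replicas)
    a2 = _rc_position_cv(rc2, scenario)
    if a2[scenario.unbind_axis] < 0:
        a2 = -a2  # orient the RC toward dissociation
    d = surface.dimension
    axis_row = np.zeros(d)
    axis_row[scenario.unbind_axis] = 1.0
    if d > 1:
        cv_prod = LinearCV(np.vstack([a2, axis_row]), names=["rc", "dist"])
        grid_lo = (scenario.cv_grid[0][0], scenario.cv_grid[1][0])
        grid_hi = (scenario.cv_grid[0][1], scenario.cv_grid[1][1])
        stop = UnbindingCriterion(scenario.unbind_threshold, cv_index=1)
    else:
        cv_prod = LinearCV(a2[None, :], names=["rc"])
        grid_lo = (scenario.cv_grid[0][0],)
        grid_hi = (scenario.cv_grid[0][1],)
        stop = UnbindingCriterion(scenario.unbind_threshold, cv_index=0)
    pparams = MetadParams(
        hill_height=config.metad.hill_height, hill_width=config.metad.hill_width,
        bias_factor=config.metad.bias_factor,
        deposition_interval=config.unbind.production_interval,
        grid_min=grid_lo, grid_max=grid_hi,
    )
    results = []
    times = []
    censored = []
    for r in range(config.unbind.n_replicas):
        res = run_unbinding(
            surface, cv_prod, pparams, stop, config.unbind.max_steps,
            seed=stage_seed(config.seed, "unbind", r), step=config.toy.step,
            friction=config.toy.friction, x0=scenario.x0,
            stride=config.unbind.stride,
        )
        results.append(res)
        times.append(
            kinetics.rescaled_time_from_run(res, beta)
            if not res.censored
            else res.trajectory.table.times[-1]
        )
        censored.append(res.censored)
    times = np.asarray(times)
    censored = np.asarray(censored)
    sample = kinetics.DissociationSample(
        times, censored, deposition_interval=config.unbind.production_interval
    )
    write_csv_table(
        TimeSeriesTable.from_arrays(
            np.arange(len(times), dtype=float),
            {"rescaled_time": times, "censored": censored.astype(float)},
        ),
        out / "unbinding_times.csv",
    )
    summary["n_censored"] = int(censored.sum())

    # -- 7. residence time ---------------------------------------------
    log.info("stage 7: Bayesian residence time")
    prior = kinetics.PriorConfig(
        cauchy_scale=config.bayes.cauchy_scale,
        log_sigma_mean=config.bayes.log_sigma_mean,
        log_sigma_sd=config.bayes.log_sigma_sd,
    )
    scfg = kinetics.SamplerConfig(
        n_walkers=config.bayes.n_walkers, n_steps=config.bayes.n_steps,
        n_burn=config.bayes.n_burn,
    )
    post = kinetics.fit_residence_time(
        sample, prior, scfg, seed=stage_seed(config.seed, "rates")
    )
    ks_d, ks_p = kinetics.ks_validate(sample, post.tau_median)
    summary.update(
        tau_median=post.tau_median, ci75_low=post.ci75[0], ci75_high=post.ci75[1],
        koff=post.koff, ks_D=ks_d, ks_p=ks_p, r_hat=post.r_hat,
    )
    (out / "rates.json").write_text(json.dumps(summary, indent=2, default=float))

    # -- 8. landscape / pathways ---------------------------------------
    log.info("stage 8: landscape characterisation")
    feats = []
    wts = []
    for res in results:
        tr = res.trajectory
        tab = _feature_table(scenario, tr, feat_rng)
        x = np.column_stack(
            [tab.values(reps), tr.positions()[:, scenario.unbind_axis]]
        )
        feats.append(x)
        wts.append(
            landscape.trajectory_frame_weights(tr, beta) * tr.n_frames
        )
    x_all = np.vstack(feats)
    w_all = np.concatenate(wts)
    w_all = w_all / w_all.sum()
    fm_l = feature_select.FeatureMatrix(
        x_all, [*reps, "dist"], frame_weights=w_all
    )
    proj = landscape.weighted_pca(fm_l)
    n_dims = min(config.landscape.n_dims, proj.scores.shape[1])
    k = landscape.select_n_clusters(
        proj.scores[:, :2],
        range(config.landscape.k_min, min(config.landscape.k_max, len(x_all) - 1) + 1),
        seed=stage_seed(config.seed, "landscape"),
    )
    fes = landscape.fit_gmm_fes(
        proj.scores[:, :n_dims], w_all, k,
        beta=beta, seed=stage_seed(config.seed, "landscape"),
        assign_dims=config.landscape.assign_dims,
    )
    minima = np.array([fes.refine_minimum(m) for m in fes.means])
    paths = {}
    for i in range(len(minima)):
        for j in range(i + 1, len(minima)):
            try:
                paths[(i, j)] = landscape.neb_mep(
                    fes, minima[i], minima[j], n_images=config.landscape.neb_images,
                    tol=config.landscape.neb_tol, min_grad_tol=1e-2,
                )
            except ValueError:
                continue
    network = landscape.kramers_rate_network(fes, minima, paths, beta=beta)
    labels = landscape.assign_states(proj.scores[:, :n_dims], fes)
    summary["n_states"] = len(minima)
    summary["rate_limiting_edge"] = (
        list(network.rate_limiting_edge) if network.rate_limiting_edge else None
    )
    (out / "landscape.json").write_text(
        json.dumps(
            {
                "surface": fes.to_dict(),
                "minima": minima.tolist(),
                "rates": network.rates.tolist(),
                "mfpt": network.mfpt.tolist(),
                "rate_limiting_edge": summary["rate_limiting_edge"],
            },
            indent=2,
        )
    )

    # -- 9. state-conditioned contact report ---------------------------
    log.info("stage 9: contact fractions")
    pos_all = np.vstack([res.trajectory.positions() for res in results])
    dists = 10.0 * np.linalg.norm(
        pos_all[:, None, :] - scenario.contact_sites[None, :, :], axis=2
    )  # pseudo-Angstrom channels
    site_names = [f"site{q+1}" for q in range(dists.shape[1])]
    contact_rows = {}
    for state in range(len(minima)):
        mask = labels == state
        if not np.any(mask):
            continue
        prof = cvmod.contact_fractions(
            dists[mask], site_names, frame_weights=w_all[mask],
            cutoff=config.contacts.cutoff,
            display_threshold=config.contacts.display_threshold,
        )
        contact_rows[f"state{state}"] = prof.fractions
    (out / "contacts.json").write_text(json.dumps(contact_rows, indent=2))
    summary["contacts"] = contact_rows

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    _write_manifest(out, "pipeline", {"config": config.to_dict()})
    log.info("pipeline complete: tau=%.3g koff=%.3g", post.tau_median, post.koff)
    return summary


# ======================================================================
# Fixtures
# ======================================================================

def fixture_generator(spec: str, seed: int, out_dir: str | Path) -> dict:
    """Deterministic bundle of small test inputs for a packaged scenario.

    Returns the manifest (also written as ``manifest.json``).  Identical
    (spec, seed) produce byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    if spec in ("double-well-1d", "three-state-2d", "double-well-1D", "three-state-2D"):
        scenario = make_scenario(spec, seed)
        (out / "surface.json").write_text(json.dumps(scenario.surface.to_dict(), indent=2))
        files.append("surface.json")
        rng = np.random.default_rng(stage_seed(seed, "fixtures"))
        cv = LinearCV.coordinate(scenario.surface.dimension, scenario.unbind_axis)
        lo, hi = scenario.cv_grid[0]
        params = MetadParams(
            hill_height=0.4, hill_width=0.15, bias_factor=12.0,
            deposition_interval=0.5, grid_min=(lo,), grid_max=(hi,),
        )
        stop = UnbindingCriterion(scenario.unbind_threshold, cv_index=0)
        for r in range(15):
            res = run_unbinding(
                scenario.surface, cv, params, stop, max_steps=400_000,
                seed=stage_seed(seed, "fixtures", r + 1), step=0.002,
                x0=scenario.x0, stride=10,
            )
            tab = _feature_table(scenario, res.trajectory, rng)
            name = f"run{r:02d}.colvar"
            write_colvar(tab, out / name)
            files.append(name)
    elif spec == "planted-feature-blocks":
        rng = np.random.default_rng(stage_seed(seed, "fixtures"))
        n = 2000
        signals = rng.standard_normal((3, n)).cumsum(axis=1) * 0.05
        cols = {}
        for b in range(3):
            for c in range(5):
                cols[f"f{b+1}{c+1}"] = signals[b] + 0.1 * rng.standard_normal(n)
        tab = TimeSeriesTable.from_arrays(np.arange(n, dtype=float), cols)
        write_csv_table(tab, out / "features.csv")
        files.append("features.csv")
    else:
        raise KeyError(f"unknown scenario '{spec}'")
    manifest = {"scenario": spec, "seed": seed, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
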