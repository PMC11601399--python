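"""Training loops and the behavioral analysis suite.

Covers everything reported for the continuous-report task: error histograms
with a uniform + circular-normal mixture fit of the guess rate, stripe usage
and giving-up, out-of-cluster-variance (OCV) conditioning, gating-policy
traces, dopamine burst/dip gain sweeps, recency curves, the mean number of
output-gated stripes, and the analytic chance-recall probability for random
gating policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .circuit import Network
from .config import ExperimentConfig
from .learning import DopamineParams
from .task import make_episode

__all__ = [
    "TrainingRun",
    "build_network",
    "train_network",
    "evaluate_network",
    "gating_policy",
    "gating_policy_trace",
    "GatingPolicySnapshot",
    "error_histogram_and_guess_rate",
    "fit_guess_rate",
    "stripe_usage",
    "ocv",
    "ocv_binned_error",
    "chance_recall_probability",
    "da_gain_sweep",
    "recency_curve",
    "mean_output_gated",
    "nonresponse_rate",
    "save_network",
    "load_network",
]


# --------------------------------------------------------------------- #
# training and evaluation
# --------------------------------------------------------------------- #


@dataclass
class TrainingRun:
    """A trained network together with its per-epoch logs."""

    config: ExperimentConfig
    seed: int
    network: Network
    epoch_log: pd.DataFrame
    snapshots: list = field(default_factory=list)  # (epoch, go_in, nogo_in)


def build_network(config: ExperimentConfig, rng: np.random.Generator) -> Network:
    return Network(
        n_stripes=config.n_stripes,
        n_orientations=config.n_orientations,
        chunk_enabled=config.chunk_enabled,
        ring_size=config.ring_size,
        tuning_width=config.tuning_width,
        noise_sd=config.noise_sd,
        lr_w=config.lr_w,
        lr_sup=config.lr_sup,
        w_max=config.w_max,
        tag_decay=config.tag_decay,
        closed_tag_gain=config.closed_tag_gain,
        lr_v=config.lr_v,
        dopamine=DopamineParams(config.burst_gain, config.dip_gain),
        input_scale=config.input_scale,
        top_down_scale=config.top_down_scale,
        n_cycles=config.n_cycles,
        maintenance_leak=config.maintenance_leak,
        rng=rng,
    )


def _draw_load(config: ExperimentConfig, rng) -> int:
    if config.variable_load and config.set_size > 1:
        return int(rng.integers(1, config.set_size + 1))
    return config.set_size


def _run_block(network, config, rng, n_trials=None, n_episodes=None, learn=True):
    """Run episodes until a trial or episode budget is exhausted."""
    results, occupancies, loads = [], [], []
    trials_done = episodes_done = 0
    while True:
        if n_trials is not None and trials_done >= n_trials:
            break
        if n_episodes is not None and episodes_done >= n_episodes:
            break
        load = _draw_load(config, rng)
        episode = make_episode(
            load, config.n_orientations, rng,
            config.ring_size, config.tuning_width,
        )
        result, occupancy, _ = network.run_episode(episode, rng, learn=learn)
        result.episode_id = episodes_done
        results.append(result)
        occupancies.append(occupancy)
        loads.append(load)
        trials_done += len(episode.trials)
        episodes_done += 1
    return results, occupancies, loads


def train_network(config: ExperimentConfig, seed: int) -> TrainingRun:
    """Train one network for ``config.n_epochs`` epochs of
    ``config.trials_per_epoch`` trials; fully reproducible from the seed."""
    ss = np.random.SeedSequence(seed)
    init_rng, trial_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    network = build_network(config, init_rng)
    rows, snapshots = [], []
    for epoch in range(config.n_epochs):
        results, occupancies, loads = _run_block(
            network, config, trial_rng,
            n_trials=config.trials_per_epoch, learn=True,
        )
        errors = np.array([r.error_deg for r in results])
        responded = np.array([r.responded for r in results])
        alpha = gating_policy(network.go_in, network.nogo_in)
        row = {
            "epoch": epoch,
            "mean_abs_error": float(np.mean(np.abs(errors))),
            "responded_rate": float(responded.mean()),
            "mean_reward": float(np.mean([r.reward for r in results])),
            "mean_output_gated": float(
                np.mean([r.n_output_gated for r in results])
            ),
            "critic_v": network.critic.v,
        }
        usage, empty_prop = stripe_usage(occupancies, loads, config.set_size)
        for j in range(config.n_stripes):
            row[f"alpha_{j}"] = float(alpha[j])
            row[f"usage_{j}"] = float(usage[j]) if usage.size else np.nan
        row["empty_stripe_prop"] = empty_prop
        rows.append(row)
        snapshots.append((epoch, network.go_in.copy(), network.nogo_in.copy()))
    return TrainingRun(config, seed, network, pd.DataFrame(rows), snapshots)


def evaluate_network(
    network: Network,
    config: ExperimentConfig,
    seed: int,
    n_episodes: int | None = None,
):
    """Run a frozen-weights evaluation block (exploration noise stays on).

    Returns (recall results, per-episode occupancy flags, episode loads).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_episodes is None:
        n_episodes = config.eval_episodes
    return _run_block(network, config, rng, n_episodes=n_episodes, learn=False)


# --------------------------------------------------------------------- #
# gating policy (opponent weight summaries)
# --------------------------------------------------------------------- #


@dataclass
class GatingPolicySnapshot:
    epoch: int
    sum_go: np.ndarray
    sum_nogo: np.ndarray
    alpha: np.ndarray


def gating_policy(go_w: np.ndarray, nogo_w: np.ndarray) -> np.ndarray:
    """Rectified normalized Go-minus-NoGo weight difference per stripe.

    ``alpha_j = [sum(Go_j) - sum(NoGo_j)]+ / (sum(Go_j) + sum(NoGo_j))``;
    defined as 0 when both sums vanish (no net drive to the thalamus) and
    invariant to uniform rescaling of all weights.
    """
    sum_go = np.asarray(go_w, dtype=float).sum(axis=0)
    sum_nogo = np.asarray(nogo_w, dtype=float).sum(axis=0)
    total = sum_go + sum_nogo
    alpha = np.zeros_like(total)
    nz = total > 0
    alpha[nz] = np.maximum(sum_go[nz] - sum_nogo[nz], 0.0) / total[nz]
    return alpha


def gating_policy_trace(snapshots) -> pd.DataFrame:
    """Eq.-style gating-policy summary per stripe per snapshot epoch."""
    rows = []
    for epoch, go_w, nogo_w in snapshots:
        alpha = gating_policy(go_w, nogo_w)
        sum_go = np.asarray(go_w).sum(axis=0)
        sum_nogo = np.asarray(nogo_w).sum(axis=0)
        for j in range(alpha.size):
            rows.append(
                {
                    "epoch": epoch,
                    "stripe": j,
                    "sum_go": sum_go[j],
                    "sum_nogo": sum_nogo[j],
                    "alpha": alpha[j],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# error distributions
# --------------------------------------------------------------------- #


def fit_guess_rate(errors_deg: np.ndarray) -> tuple:
    """Maximum-likelihood uniform + circular-normal (von Mises) mixture.

    Returns (guess_rate, kappa): the weight of the uniform component in
    [0, 1] and the concentration of the zero-centered von Mises component.
    """
    x = np.radians(np.asarray(errors_deg, dtype=float))

    def nll(params):
        g, log_kappa = params
        kappa = np.exp(log_kappa)
        pdf = g / (2 * np.pi) + (1 - g) * stats.vonmises.pdf(x, kappa)
        return -np.sum(np.log(np.maximum(pdf, 1e-300)))

    best = None
    for g0 in (0.1, 0.5, 0.9):
        for k0 in (2.0, 20.0, 80.0):
            res = optimize.minimize(
                nll,
                x0=[g0, np.log(k0)],
                bounds=[(0.0, 1.0), (np.log(0.5), np.log(500.0))],
                method="L-BFGS-B",
            )
            if best is None or res.fun < best.fun:
                best = res
    g, log_kappa = best.x
    return float(g), float(np.exp(log_kappa))


def error_histogram_and_guess_rate(results, bin_width_deg: float = 10.0):
    """Binned signed-error histogram plus the mixture guess-rate estimate.

    ``results`` may be RecallResults or a bare array of signed errors in
    degrees.  Fewer than 100 trials flags the estimate as low-confidence.
    """
    if hasattr(results, "__len__") and len(results) and hasattr(
        results[0], "error_deg"
    ):
        errors = np.array([r.error_deg for r in results])
    else:
        errors = np.asarray(results, dtype=float)
    edges = np.arange(-180.0, 180.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(errors, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    guess_rate, kappa = fit_guess_rate(errors)
    return {
        "histogram": hist,
        "guess_rate": guess_rate,
        "kappa": kappa,
        "n": errors.size,
        "low_confidence": errors.size < 100,
    }


# --------------------------------------------------------------------- #
# resource usage
# --------------------------------------------------------------------- #


def stripe_usage(occupancies, loads, set_size: int):
    """Occupancy statistics on maximum-load episodes.

    Returns (per-stripe fraction occupied after the final store trial,
    proportion of episodes with at least one empty stripe); both measured
    only on episodes that presented ``set_size`` items.
    """
    occ = [o for o, l in zip(occupancies, loads) if l == set_size]
    if not occ:
        return np.array([]), float("nan")
    mat = np.array(occ, dtype=float)
    return mat.mean(axis=0), float(np.mean(1.0 - mat.min(axis=1)))


def mean_output_gated(results) -> float:
    """Average number of stripes opened by output gating per recall trial."""
    return float(np.mean([r.n_output_gated for r in results]))


def nonresponse_rate(results) -> float:
    """Fraction of recall trials that produced no response."""
    return float(np.mean([not r.responded for r in results]))


# --------------------------------------------------------------------- #
# out-of-cluster variance
# --------------------------------------------------------------------- #


def ocv(other_item_angles) -> float:
    """Circular standard deviation (degrees) of the non-probed items."""
    angles = np.asarray(other_item_angles, dtype=float)
    if angles.size < 2:
        raise ValueError("OCV requires at least two non-probed items")
    r = np.abs(np.mean(np.exp(1j * angles)))
    r = min(r, 1.0)
    if r <= 1e-12:
        return float(np.degrees(np.sqrt(-2.0 * np.log(1e-12))))
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def ocv_binned_error(results_by_model: dict, bins) -> pd.DataFrame:
    """Mean absolute recall error per OCV bin for each model.

    ``bins`` is an array of bin edges in degrees.  Empty bins are reported
    with NaN means (missing, not zero).
    """
    edges = np.asarray(bins, dtype=float)
    rows = []
    for model, results in results_by_model.items():
        vals = [
            (ocv(r.other_item_angles), abs(r.error_deg))
            for r in results
            if len(r.other_item_angles) >= 2
        ]
        ocvs = np.array([v[0] for v in vals])
        errs = np.array([v[1] for v in vals])
        idx = np.digitize(ocvs, edges) - 1
        for b in range(edges.size - 1):
            sel = idx == b
            rows.append(
                {
                    "model": model,
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "mean_abs_error": float(errs[sel].mean())
                    if sel.any()
                    else float("nan"),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# analytic chance recall
# --------------------------------------------------------------------- #


def chance_recall_probability(n_stripes: int, set_size: int) -> float:
    """Probability that a random gating policy recalls the first item.

    Each of the ``N`` items is gated into one of ``n`` stripes uniformly at
    random (overwriting), and one stripe is read out uniformly at random;
    success requires the first item to survive all later placements and to
    be the stripe read out: ``(n-1)^(N-1) / n^N`` (``1/n`` when ``N = 1``).
    """
    n, N = n_stripes, set_size
    if n < 1 or N < 1:
        raise ValueError("n_stripes and set_size must be >= 1")
    return float((n - 1) ** (N - 1) / n**N)


# --------------------------------------------------------------------- #
# dopamine gain sweep
# --------------------------------------------------------------------- #


def da_gain_sweep(
    base_config: ExperimentConfig,
    burst_grid,
    dip_grid,
    seeds=None,
    eval_episodes: int | None = None,
) -> pd.DataFrame:
    """Mean absolute recall error over a grid of burst/dip gain pairs.

    Trains ``seeds`` fresh networks per cell and evaluates each with frozen
    weights; divergent runs are recorded as NaN rather than dropped.
    """
    if seeds is None:
        seeds = base_config.seeds
    rows = []
    for burst in burst_grid:
        for dip in dip_grid:
            cfg = base_config.replace(burst_gain=burst, dip_gain=dip)
            errs = []
            for seed in seeds:
                try:
                    run = train_network(cfg, seed)
                    results, _, _ = evaluate_network(
                        run.network, cfg, seed + 1, eval_episodes
                    )
                    errs.extend(abs(r.error_deg) for r in results)
                except FloatingPointError:
                    errs = None
                    break
            rows.append(
                {
                    "burst_gain": burst,
                    "dip_gain": dip,
                    "mean_abs_error": float(np.mean(errs))
                    if errs
                    else float("nan"),
                    "n_trials": len(errs) if errs else 0,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# recency
# --------------------------------------------------------------------- #


def save_network(network: Network, config: ExperimentConfig, path):
    """Persist a network's learned weights plus its config to one .npz file.

    Only the learned state is stored (striatal Go/NoGo matrices, report
    mappings, critic expectation); the architecture is rebuilt from the
    embedded config on load.
    """
    import json

    np.savez(
        path,
        go_in=network.go_in,
        nogo_in=network.nogo_in,
        go_out=network.go_out,
        nogo_out=network.nogo_out,
        W_in_out=network.W_in_out,
        W_pfc_out=network.W_pfc_out,
        critic_values=np.asarray(network.critic.values),
        config_json=np.array(json.dumps(config.to_dict())),
    )


def load_network(path):
    """Rebuild a (network, config) pair saved by :func:`save_network`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        config = ExperimentConfig(**json.loads(str(data["config_json"])))
        network = build_network(config, np.random.default_rng(0))
        network.go_in = data["go_in"].copy()
        network.nogo_in = data["nogo_in"].copy()
        network.go_out = data["go_out"].copy()
        network.nogo_out = data["nogo_out"].copy()
        network.W_in_out = data["W_in_out"].copy()
        network.W_pfc_out = data["W_pfc_out"].copy()
        network.critic.values = data["critic_values"].copy()
    return network, config


def recency_curve(results) -> pd.DataFrame:
    """Mean absolute recall error as a function of storage-to-probe lag."""
    lags = np.array([r.lag for r in results])
    errs = np.array([abs(r.error_deg) for r in results])
    rows = [
        {
            "lag": int(l),
            "mean_abs_error": float(errs[lags == l].mean()),
            "n": int(np.sum(lags == l)),
        }
        for l in np.unique(lags)
    ]
    return pd.DataFrame(rows)
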