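"""Experiment orchestration at desk scale.

Wires the pieces together the way the study design does: generate (or
load) a drug-response panel, fit the REFINED maps on the server's small
initial set DT(I) only, broadcast them, pretrain the server model,
then run any of: the federated loop, a centralized benchmark on the
pooled training data, or individually trained per-client baselines —
all evaluated on the common hold-out DH and averaged over replicate
data partitions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .federation import FedConfig, fit_centralized, pretrain_server, run_federation
from .metrics import nrmse, pcc, replicate_summary
from .models import Dataset, ModelConfig, build_model, child_rng
from .refined import RefinedMap, fit_refined_map, to_image
from .synth import SyntheticStudy, generate_study, permute_targets, split_quasi_random, split_random

__all__ = [
    "ExperimentConfig",
    "InputPipeline",
    "ComparisonReport",
    "build_pipeline",
    "run_client_baselines",
    "run_experiment",
    "relative_improvement",
    "heterogeneity_sweep",
    "federation_benefit_study",
]


@dataclass
class InputPipeline:
    """Feature scaling + REFINED maps fitted on DT(I), applied everywhere.

    Holds the column means/sds of the cell and drug feature matrices and
    the target mean/sd (all estimated from the server's initial samples)
    plus, for image models, one REFINED map per arm.
    """

    kind: str
    cell_stats: tuple
    drug_stats: tuple
    y_stats: tuple
    cell_map: RefinedMap | None = None
    drug_map: RefinedMap | None = None

    def input_spec(self) -> dict:
        if self.kind == "ann":
            p = len(self.cell_stats[0]) + len(self.drug_stats[0])
            return {"flat": (p,)}
        g_c, g_d = self.cell_map.grid_side, self.drug_map.grid_side
        return {"cell": (1, g_c, g_c), "drug": (1, g_d, g_d)}

    def _scale(self, X, stats):
        mu, sd = stats
        return (X - mu) / sd

    def dataset(self, study: SyntheticStudy, idx, y_override=None) -> Dataset:
        idx = np.asarray(idx)
        Xc, Xd = study.sample_features(idx)
        Zc = self._scale(Xc, self.cell_stats)
        Zd = self._scale(Xd, self.drug_stats)
        y = study.y[idx] if y_override is None else np.asarray(y_override)
        y_mu, y_sd = self.y_stats
        yz = (y - y_mu) / y_sd
        if self.kind == "ann":
            return Dataset({"flat": np.concatenate([Zc, Zd], axis=1)}, yz)
        imgs_c = to_image(Zc, self.cell_map)[:, None, :, :]
        imgs_d = to_image(Zd, self.drug_map)[:, None, :, :]
        return Dataset({"cell": imgs_c, "drug": imgs_d}, yz)


def _col_stats(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


def build_pipeline(study: SyntheticStudy, dt_i_idx, kind: str, seed: int = 0,
                   map_iters: int = 20) -> InputPipeline:
    """Fit scalers (and REFINED maps for image models) on the server set only."""
    Xc, Xd = study.sample_features(dt_i_idx)
    cell_stats = _col_stats(Xc)
    drug_stats = _col_stats(Xd)
    y_stats = _col_stats(study.y[np.asarray(dt_i_idx)].reshape(-1, 1))
    y_stats = (float(y_stats[0][0]), float(y_stats[1][0]))
    cell_map = drug_map = None
    if kind != "ann":
        # de-duplicate repeated cell/drug rows before the distance computation
        cell_map = fit_refined_map(np.unique(Xc, axis=0), seed=seed, max_iters=map_iters)
        drug_map = fit_refined_map(np.unique(Xd, axis=0), seed=seed + 1, max_iters=map_iters)
    return InputPipeline(kind=kind, cell_stats=cell_stats, drug_stats=drug_stats,
                         y_stats=y_stats, cell_map=cell_map, drug_map=drug_map)


@dataclass(frozen=True)
class ExperimentConfig:
    """One study design: which model, partition, and training arms to run."""

    model: str = "refined_drf"
    n_clients: int = 5
    rounds: int = 25
    pretrain_epochs: int = 30
    baseline_epochs: int = 40
    partition_mode: str = "random"  # random | quasi_random
    k: int | None = None
    federation_mode: str = "standard"  # standard | personalized
    replicate_seeds: tuple = (0, 1, 2)
    run_federated: bool = True
    run_centralized: bool = False
    run_clients: bool = False
    run_initial: bool = True
    permute_fraction: float = 0.0
    local_test_frac: float = 0.0  # >0 adds per-client local hold-outs (Table-1 design)
    study_kwargs: dict = field(default_factory=dict)
    model_config: ModelConfig | None = None
    fed_config: FedConfig | None = None
    outdir: str | None = None

    def resolved_model_config(self) -> ModelConfig:
        if self.model_config is not None:
            return self.model_config
        return ModelConfig(kind=self.model)


@dataclass
class ComparisonReport:
    """Replicate-level metric rows, their means, and pairwise improvements."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    improvements: dict

    def to_json(self) -> str:
        return json.dumps(
            {"summary": self.summary.to_dict(orient="records"),
             "improvements": self.improvements},
            indent=2,
        )


def relative_improvement(summary: pd.DataFrame, baseline: str, other: str) -> dict:
    """Improvement of ``other`` over ``baseline``: (a-b)/a on NRMSE, (b-a)/a on PCC."""
    a = summary[summary["setting"] == baseline].iloc[0]
    b = summary[summary["setting"] == other].iloc[0]
    return {
        "baseline": baseline,
        "other": other,
        "nrmse_improvement": float((a["nrmse"] - b["nrmse"]) / a["nrmse"]),
        "pcc_improvement": float((b["pcc"] - a["pcc"]) / a["pcc"]),
    }


def _partition(study, cfg: ExperimentConfig, seed: int):
    if cfg.partition_mode == "random":
        return split_random(study, cfg.n_clients, seed=seed)
    if cfg.partition_mode == "quasi_random":
        k = cfg.k if cfg.k is not None else 2
        return split_quasi_random(study, n_clients=cfg.n_clients, k=k, seed=seed)
    raise ValueError(f"unknown partition mode {cfg.partition_mode!r}")


def run_client_baselines(
    client_datasets: list[Dataset],
    dh: Dataset,
    model_config: ModelConfig,
    input_spec: dict,
    seed: int = 0,
    epochs: int = 40,
    local_val_frac: float = 0.10,
    local_test_frac: float = 0.0,
):
    """Train one reduced-complexity model per client on its local share alone.

    Each client carves a 10% local validation subset for early stopping
    (and optionally a local hold-out) from its own data; no parameter
    exchange occurs.  Returns (models, metric rows): one ``global`` row
    per client scored on DH, plus a ``local`` row when a local hold-out
    is requested.
    """
    models, rows = [], []
    for j, data in enumerate(client_datasets):
        rng = child_rng(seed, 0xBA, j)
        perm = rng.permutation(data.n)
        n_test = int(round(local_test_frac * data.n))
        n_val = int(round(local_val_frac * data.n))
        test_idx, val_idx = perm[:n_test], perm[n_test : n_test + n_val]
        train_idx = perm[n_test + n_val :]
        train, val = data.subset(train_idx), data.subset(val_idx)
        if val.n < 2:
            import warnings

            warnings.warn(f"client {j} too small for a validation split; "
                          "training without early stopping", stacklevel=2)
            val = None
        model = build_model(model_config, input_spec, seed=int(child_rng(seed, 0xB1, j)
                                                               .integers(2**31)))
        fit_centralized(model, train, val, epochs=epochs, seed=seed + j)
        models.append(model)
        yhat = model.predict(dh)
        rows.append({"client_id": j, "scope": "global",
                     "nrmse": nrmse(dh.y, yhat), "pcc": pcc(dh.y, yhat)})
        if n_test >= 2:
            local = data.subset(test_idx)
            yl = model.predict(local)
            rows.append({"client_id": j, "scope": "local",
                         "nrmse": nrmse(local.y, yl), "pcc": pcc(local.y, yl)})
    return models, pd.DataFrame(rows)


def _eval_row(model, dh: Dataset, setting: str, cfg: ExperimentConfig, rep: int) -> dict:
    yhat = model.predict(dh)
    return {"model": cfg.model, "setting": setting, "n_clients": cfg.n_clients,
            "replicate": rep, "nrmse": nrmse(dh.y, yhat), "pcc": pcc(dh.y, yhat)}


def run_replicate(cfg: ExperimentConfig, seed: int, rep: int) -> tuple[list[dict], dict]:
    """One replicate: generate, partition, map, pretrain, train all arms."""
    mc = cfg.resolved_model_config()
    study = generate_study(seed=seed, **cfg.study_kwargs)
    part = _partition(study, cfg, seed)
    pipe = build_pipeline(study, part.dt_i, mc.kind, seed=seed)
    spec = pipe.input_spec()

    dt_i = pipe.dataset(study, part.dt_i)
    dv = pipe.dataset(study, part.dv)
    dh = pipe.dataset(study, part.dh)
    clients = []
    for j, idx in enumerate(part.client_shares):
        y_local = study.y[idx]
        if cfg.permute_fraction > 0:
            y_local = permute_targets(y_local, cfg.permute_fraction, seed=seed * 1000 + j)
        clients.append(pipe.dataset(study, idx, y_override=y_local))

    rows, artifacts = [], {}
    model = build_model(mc, spec, seed=seed)
    model = pretrain_server(model, dt_i, dv, epochs=cfg.pretrain_epochs, seed=seed)
    if cfg.run_initial:
        rows.append(_eval_row(model, dh, "initial", cfg, rep))

    if cfg.run_centralized:
        central = build_model(mc, spec, seed=seed)
        pooled_idx = np.concatenate([part.dt_i, *part.client_shares])
        pooled = pipe.dataset(study, pooled_idx)
        fit_centralized(central, pooled, dv, epochs=cfg.rounds, seed=seed)
        rows.append(_eval_row(central, dh, "centralized", cfg, rep))

    if cfg.run_federated:
        fed_cfg = cfg.fed_config or FedConfig(rounds=cfg.rounds, mode=cfg.federation_mode)
        result = run_federation(model.clone(), clients, dv, fed_cfg, seed=seed)
        rows.append(_eval_row(result.model, dh, "federated", cfg, rep))
        artifacts["round_log"] = result.log
        artifacts["federation"] = result

    if cfg.run_clients:
        _, client_rows = run_client_baselines(
            clients, dh, mc.reduced(), spec, seed=seed, epochs=cfg.baseline_epochs,
            local_test_frac=cfg.local_test_frac,
        )
        grows = client_rows[client_rows["scope"] == "global"]
        rows.append({"model": cfg.model, "setting": "clients_mean",
                     "n_clients": cfg.n_clients, "replicate": rep,
                     "nrmse": float(grows["nrmse"].mean()),
                     "pcc": float(grows["pcc"].mean())})
        artifacts["client_rows"] = client_rows
    return rows, artifacts


def run_experiment(cfg: ExperimentConfig) -> ComparisonReport:
    """Run all replicates and aggregate into a comparison report."""
    all_rows, logs = [], []
    for rep, seed in enumerate(cfg.replicate_seeds):
        rows, artifacts = run_replicate(cfg, int(seed), rep)
        all_rows.extend(rows)
        if "round_log" in artifacts:
            log = artifacts["round_log"].copy()
            log["replicate"] = rep
            logs.append(log)
    rows = pd.DataFrame(all_rows)
    summary = replicate_summary(all_rows)
    improvements = {}
    settings = set(summary["setting"])
    for baseline, other in [("initial", "federated"), ("clients_mean", "federated"),
                            ("centralized", "federated")]:
        if baseline in settings and other in settings:
            improvements[f"{other}_vs_{baseline}"] = relative_improvement(
                summary, baseline, other)

    report = ComparisonReport(rows=rows, summary=summary, improvements=improvements)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        rows.to_csv(out / "metrics.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        if logs:
            pd.concat(logs).to_csv(out / "round_log.csv", index=False)
        echo = dataclasses.asdict(cfg)
        echo["model_config"] = dataclasses.asdict(cfg.resolved_model_config())
        if cfg.fed_config is not None:
            echo["fed_config"] = dataclasses.asdict(cfg.fed_config)
        (out / "config.json").write_text(json.dumps(echo, indent=2, default=str))
        (out / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# Packaged desk-scale study presets
# ---------------------------------------------------------------------------

def heterogeneity_sweep(n_replicates: int = 20, ks=(2, 24), seed: int = 0,
                        n_clients: int = 12, rounds: int = 8) -> pd.DataFrame:
    """Quasi-random allocation sweep feeding the R-statistic diagnostic.

    For each overlap value k and replicate, runs a 12-client federation on
    a 24-drug panel partitioned so every client observes only k drugs,
    then computes the Gelman–Rubin-style R from the per-client
    validation-loss trajectories.  The panel (80 cells × 24 drugs,
    per-drug cluster offsets) is sized so each client shard is large
    enough that homogeneous (full-overlap) clients mix well, which is
    what the diagnostic's R ≈ 1 reading assumes.
    """
    from .diagnostics import r_statistic, trajectory_stats

    model_cfg = ModelConfig(kind="refined_drf", conv_filters=(), hidden=(16,),
                            trees=2, depth=3, lr=0.05, batch_size=16)
    rows = []
    for k in ks:
        for rep in range(n_replicates):
            rep_seed = int(child_rng(seed, 0x4E7, k, rep).integers(2**31))
            cfg = ExperimentConfig(
                model="refined_drf", n_clients=n_clients, rounds=rounds,
                pretrain_epochs=8, partition_mode="quasi_random", k=k,
                replicate_seeds=(rep_seed,), run_initial=False,
                study_kwargs=dict(n_cells=80, n_drugs=24, p_cell=16, p_drug=9,
                                  noise_sd=0.3, cluster_effect=1.0),
                model_config=model_cfg,
                fed_config=FedConfig(rounds=rounds, patience=10 * rounds),
            )
            _, artifacts = run_replicate(cfg, rep_seed, rep)
            traj = artifacts["federation"].client_trajectories()
            r = r_statistic(trajectory_stats(traj))
            rows.append({"k": k, "replicate": rep, "R": r})
    return pd.DataFrame(rows)


def federation_benefit_study(n_replicates: int = 10, seed: int = 0,
                             n_clients: int = 5, rounds: int = 20) -> pd.DataFrame:
    """Federated REFINED-DRF versus individually trained client models.

    Each replicate simulates a ~2000-sample panel rendered as 8×8 cell
    images (and 5×5 drug images), trains the federated model and the
    per-client reduced baselines on identical partitions, and scores
    everything on the common hold-out DH.
    """
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(child_rng(seed, 0xBE7, rep).integers(2**31))
        cfg = ExperimentConfig(
            model="refined_drf", n_clients=n_clients, rounds=rounds,
            pretrain_epochs=15, baseline_epochs=30,
            replicate_seeds=(rep_seed,), run_clients=True,
            study_kwargs=dict(n_cells=100, n_drugs=20, p_cell=64, p_drug=25,
                              noise_sd=0.3, cluster_effect=1.0),
        )
        reps, _ = run_replicate(cfg, rep_seed, rep)
        row = {"replicate": rep}
        for r in reps:
            row[f"{r['setting']}_nrmse"] = r["nrmse"]
            row[f"{r['setting']}_pcc"] = r["pcc"]
        rows.append(row)
    return pd.DataFrame(rows)
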