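"""End-to-end orchestration: simulate/load -> behavior -> PETH -> cluster -> expression.

A run is described by a :class:`RunConfig` whose tunables all default
to the analysis values (10-trial CPI blocks; -5 s..+10 s PETHs with
50-ms bins and 3-point Gaussian smoothing; Euclidean/average-linkage
clustering cut at linkage 3; 0.5-Hz unit exclusion; GAPDH
housekeeping). Every output is written under the run directory along
with the serialized configuration and its hash; rerunning the same
configuration reproduces the outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import clustering as cl
from . import expression as xp
from . import io as rio
from .ephys import (
    EventSeries,
    PETH,
    PETHConfig,
    SpikeTrain,
    ZScoredPETH,
    compute_peth,
    gaussian_smooth,
    zscore_peth,
)
from .simulate import (
    AgentParams,
    SimConfig,
    TaskContingency,
    UnitSpec,
    make_planted_units,
    simulate_ct_table,
    simulate_recording,
)

__all__ = [
    "RunConfig",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "compare_periods",
    "analyze_units",
    "config_to_dict",
    "config_from_dict",
    "load_run_config",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (paths or a simulation, plus stage parameters)."""

    out_dir: Path
    seed: int = 0
    sim: SimConfig | None = None
    trials_path: Path | None = None
    events_path: Path | None = None
    spikes_path: Path | None = None
    ct_path: Path | None = None
    ct_sim: dict | None = None  # kwargs for simulate_ct_table (sans seed)
    block_size: int = 10
    peth: PETHConfig = field(default_factory=PETHConfig)
    cluster: cl.ClusterConfig = field(default_factory=cl.ClusterConfig)
    housekeeping: str = xp.HOUSEKEEPING_DEFAULT
    post_window: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.sim is None and self.trials_path is None:
            raise ValueError("either a simulation or a trials file is required")


@dataclass(frozen=True)
class PipelineReport:
    """In-memory results plus the digests of everything written."""

    out_dir: Path
    config_hash: str
    session: bh.Session
    curve: bh.PreferenceCurve
    behavior_metrics: dict[str, Any]
    features: cl.FeatureMatrix | None
    tree: cl.ClusterTree | None
    labels: dict[str, int] | None
    cluster_mean_z: pd.DataFrame | None
    flexibility: pd.Series | None
    expression: dict[str, xp.ExpressionResult] | None
    digests: dict[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_units(
    trains: list[SpikeTrain] | tuple[SpikeTrain, ...],
    events: EventSeries,
    duration: float,
    peth_config: PETHConfig = PETHConfig(),
    cluster_config: cl.ClusterConfig = cl.ClusterConfig(),
    post_window: float = 5.0,
) -> tuple[cl.FeatureMatrix, cl.ClusterTree, dict[str, int], pd.DataFrame, pd.Series, dict[str, str]]:
    """Unit-level analysis chain shared by the pipeline and the CLI.

    Excludes low-firing units, builds raw PETHs per response class,
    forms the activity-ratio feature matrix, clusters, cuts, and
    summarizes per-cluster mean post-press Z (on the smoothed,
    Z-scored PETHs) and flexibility. Returns the intermediate objects
    and an exclusion map (unit id -> reason).
    """
    rates = {tr.unit_id: len(tr) / duration for tr in trains}
    kept_ids, low = cl.exclude_low_firing(rates, cluster_config.min_rate_hz)
    excluded: dict[str, str] = {u: f"low_rate({r:.3g}Hz)" for u, r in low}
    kept = [tr for tr in trains if tr.unit_id in set(kept_ids)]
    if len(kept) < 2:
        raise ValueError("fewer than two units survive the firing-rate exclusion")
    raw: dict[str, dict[str, PETH]] = {}
    zped: dict[str, dict[str, ZScoredPETH]] = {}
    for tr in kept:
        raw[tr.unit_id] = {}
        zped[tr.unit_id] = {}
        for cls in cl.RESPONSE_CLASSES:
            peth = compute_peth(tr, events, class_filter=cls, config=peth_config)
            raw[tr.unit_id][cls] = peth
            if not peth.is_empty:
                smoothed = gaussian_smooth(peth, peth_config.smooth_points)
                zped[tr.unit_id][cls] = zscore_peth(smoothed)
    features = cl.build_features(raw, window=post_window)
    tree = cl.hierarchical_cluster(features, cluster_config)
    excluded.update(tree.excluded)
    labels = cl.cut_tree(tree, cluster_config.cut_threshold)
    mean_z = cl.cluster_mean_z(labels, zped, window=(0.0, post_window))
    flexibility = pd.Series(
        {c: cl.flexibility_score(mean_z.loc[c]) for c in mean_z.index},
        name="flexibility",
    )
    flexibility.index.name = "cluster"
    return features, tree, labels, mean_z, flexibility, excluded


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the configured stages and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config_to_dict(config)
    cfg_text = yaml.safe_dump(cfg_dict, sort_keys=True)
    # hash identifies the analysis configuration, not where it is written
    hashed = {k: v for k, v in cfg_dict.items() if k != "out"}
    config_hash = hashlib.sha256(
        yaml.safe_dump(hashed, sort_keys=True).encode()
    ).hexdigest()
    (out / "config.yaml").write_text(cfg_text)

    # --- data stage -----------------------------------------------------
    trains: tuple[SpikeTrain, ...] | list[SpikeTrain] = ()
    duration = 0.0
    events: EventSeries | None = None
    try:
        if config.sim is not None:
            rec = simulate_recording(config.sim)
            session, events, trains, duration = (
                rec.session,
                rec.events,
                rec.spike_trains,
                rec.duration,
            )
            rio.write_trials(session, out / "trials.csv")
            rio.write_events(events, out / "events.csv")
            if trains:
                rio.write_spikes(list(trains), out / "spikes.csv")
        else:
            session = rio.read_trials(config.trials_path)
            if config.events_path is not None:
                events = rio.read_events(config.events_path)
            if config.spikes_path is not None:
                trains = rio.read_spikes(config.spikes_path)
                last = max((tr.timestamps[-1] for tr in trains if len(tr)), default=0.0)
                duration = float(last) + 10.0
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - halting with stage context
        raise PipelineError("data", str(exc)) from exc

    # --- behavior stage -------------------------------------------------
    try:
        curve = bh.preference_curve(session, block_size=config.block_size)
        lat = bh.latency_summary(session)
        metrics = {
            "cpi_session": bh.choice_preference_index(session.trials),
            "omission_rate_pct": bh.omission_rate(session),
            "latency_mean_s": lat.mean,
            "latency_sd_s": lat.sd,
            "n_trials": len(session),
            "n_completed": len(session.completed),
        }
        pd.DataFrame(
            {
                "block": curve.block_indices,
                "cpi": curve.cpi_values,
                "cpi_smoothed": curve.smoothed,
            }
        ).to_csv(out / "preference_curve.csv", index=False)
        pd.Series(bh.response_map(session), name="code").rename_axis("trial").to_csv(
            out / "response_map.csv"
        )
        (out / "behavior_metrics.json").write_text(
            json.dumps(metrics, indent=2, default=float)
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("behavior", str(exc)) from exc

    # --- ephys + clustering stages --------------------------------------
    features = tree = labels = mean_z = flexibility = None
    if trains and events is not None and len(events):
        try:
            features, tree, labels, mean_z, flexibility, excluded = analyze_units(
                trains,
                events,
                duration,
                peth_config=config.peth,
                cluster_config=config.cluster,
                post_window=config.post_window,
            )
            features.values.rename_axis("unit_id").to_csv(out / "features.csv")
            pd.DataFrame(
                tree.merges, columns=["left", "right", "distance", "size"]
            ).to_csv(out / "merge_tree.csv", index=False)
            pd.Series(labels, name="cluster").rename_axis("unit_id").to_csv(
                out / "labels.csv"
            )
            mean_z.to_csv(out / "cluster_mean_z.csv")
            flexibility.to_csv(out / "flexibility.csv")
            pd.Series(excluded, name="reason").rename_axis("unit_id").to_csv(
                out / "excluded_units.csv"
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("cluster", str(exc)) from exc

    # --- expression stage -----------------------------------------------
    expression = None
    try:
        ct = None
        if config.ct_path is not None:
            ct = rio.read_ct(config.ct_path)
        elif config.ct_sim is not None:
            ct = simulate_ct_table(
                seed=config.seed, housekeeping=config.housekeeping, **config.ct_sim
            )
            rio.write_ct(ct, out / "ct.csv")
        if ct is not None:
            expression = {}
            rows = []
            for gene in sorted(set(ct["gene"]) - {config.housekeeping}):
                res = xp.relative_expression(
                    ct, housekeeping=config.housekeeping, target=gene
                )
                expression[gene] = res
                per = res.per_group.copy()
                per.insert(0, "gene", gene)
                rows.append(per)
            pd.concat(rows, ignore_index=True).to_csv(
                out / "expression_groups.csv", index=False
            )
            pd.concat(
                [r.per_sample.assign(gene=g) for g, r in expression.items()],
                ignore_index=True,
            ).to_csv(out / "expression_samples.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression", str(exc)) from exc

    digests = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in {".csv", ".json"}
    }
    (out / "report.json").write_text(
        json.dumps({"config_hash": config_hash, "digests": digests}, indent=2)
    )
    return PipelineReport(
        out_dir=out,
        config_hash=config_hash,
        session=session,
        curve=curve,
        behavior_metrics=metrics,
        features=features,
        tree=tree,
        labels=labels,
        cluster_mean_z=mean_z,
        flexibility=flexibility,
        expression=expression,
        digests=digests,
    )


def compare_periods(
    control: pd.DataFrame | PipelineReport, pain: pd.DataFrame | PipelineReport
) -> pd.DataFrame:
    """Per-cluster, per-class change in mean Z between two periods.

    Clusters are re-derived independently per period, so rows are
    matched by profile similarity: each control cluster is paired with
    the pain cluster whose mean-Z profile is nearest (Euclidean, NaN
    treated as 0 for the distance only). A non-bijective matching
    triggers a warning. Returns a table indexed by control cluster with
    the matched pain cluster and the delta (pain - control) per class.
    """
    a = control.cluster_mean_z if isinstance(control, PipelineReport) else control
    b = pain.cluster_mean_z if isinstance(pain, PipelineReport) else pain
    if a is None or b is None:
        raise ValueError("both periods need cluster mean-Z tables")
    A = a.to_numpy(dtype=float)
    B = b.to_numpy(dtype=float)
    A0 = np.nan_to_num(A)
    B0 = np.nan_to_num(B)
    matches = []
    for i in range(A0.shape[0]):
        dists = np.linalg.norm(B0 - A0[i], axis=1)
        matches.append(int(np.argmin(dists)))
    if len(set(matches)) != len(matches) or A0.shape[0] != B0.shape[0]:
        warnings.warn(
            "cluster sets do not match one-to-one; matched by nearest profile",
            stacklevel=2,
        )
    out = pd.DataFrame(index=a.index.copy())
    out["matched_cluster"] = [b.index[m] for m in matches]
    for j, cls in enumerate(a.columns):
        out[f"delta_{cls}"] = [B[m, j] - A[i, j] for i, m in enumerate(matches)]
    out.index.name = "control_cluster"
    return out


# --- configuration (de)serialization ------------------------------------


def config_to_dict(config: RunConfig) -> dict:
    """Round-trippable plain-dict form of a RunConfig."""
    d: dict[str, Any] = {
        "out": str(config.out_dir),
        "seed": config.seed,
        "block_size": config.block_size,
        "housekeeping": config.housekeeping,
        "post_window": config.post_window,
        "peth": asdict(config.peth),
        "cluster": asdict(config.cluster),
    }
    for key in ("trials_path", "events_path", "spikes_path", "ct_path"):
        v = getattr(config, key)
        if v is not None:
            d[key.removesuffix("_path")] = str(v)
    if config.ct_sim is not None:
        d["ct_sim"] = config.ct_sim
    if config.sim is not None:
        sim = config.sim
        d["simulate"] = {
            "seed": sim.seed,
            "session_padding": sim.session_padding,
            "contingency": asdict(sim.contingency),
            "agent": asdict(sim.agent),
            "units": [
                {
                    "unit_id": u.unit_id,
                    "baseline_rate": u.baseline_rate,
                    "gains": dict(u.gain_by_response),
                    "cluster_id": u.cluster_id,
                }
                for u in sim.units
            ],
        }
    return d


def config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    """Inverse of :func:`config_to_dict`; also accepts a ``planted`` unit spec."""
    sim = None
    if "simulate" in d:
        s = d["simulate"]
        if "planted" in s:
            p = dict(s["planted"])
            units = make_planted_units(
                n_per_cluster=p["n_per_cluster"],
                cluster_gains=p["cluster_gains"],
                baseline_rate=p.get("baseline_rate", 8.0),
            )
        else:
            units = [
                UnitSpec(
                    unit_id=u["unit_id"],
                    baseline_rate=u["baseline_rate"],
                    gain_by_response=u.get("gains", {}),
                    cluster_id=u.get("cluster_id", 0),
                )
                for u in s.get("units", [])
            ]
        sim = SimConfig(
            contingency=TaskContingency(**s.get("contingency", {})),
            agent=AgentParams(**s.get("agent", {})),
            units=tuple(units),
            seed=int(s.get("seed", d.get("seed", 0))),
            session_padding=float(s.get("session_padding", 10.0)),
        )
    kwargs: dict[str, Any] = {}
    for key in ("trials", "events", "spikes", "ct"):
        if key in d:
            kwargs[f"{key}_path"] = Path(d[key])
    return RunConfig(
        out_dir=Path(d["out"]),
        seed=int(d.get("seed", 0)),
        sim=sim,
        ct_sim=d.get("ct_sim"),
        block_size=int(d.get("block_size", 10)),
        peth=PETHConfig(**d.get("peth", {})),
        cluster=cl.ClusterConfig(**d.get("cluster", {})),
        housekeeping=str(d.get("housekeeping", xp.HOUSEKEEPING_DEFAULT)),
        post_window=float(d.get("post_window", 5.0)),
        **kwargs,
    )


def load_run_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load a YAML run configuration, applying keyword overrides."""
    d = dict(yaml.safe_load(Path(path).read_text()))
    d.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(d)
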