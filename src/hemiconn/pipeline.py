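"""End-to-end orchestration: cohort -> connectomes -> four-network prediction.

Runs the full analysis behind a single config: obtain a cohort (simulated or
loaded from ROI time-series files), compute Pearson connectivity, split the
edges into the LH/RH/Ho/He networks, run forest screening + nested-LOOCV
ridge per network, and emit importance tables, per-subject predictions,
top-k connection reports and a checksummed manifest. Group analyses split
the cohort by age (two halves as even as possible) or sex, screen features
once on the full cohort (inter-group screening) and evaluate each group
separately on the shared edge set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    Atlas, GYRUS_ABBREVS, GYRUS_NAMES, LOBE_NAMES, NETWORKS, Network,
    load_atlas, load_bundled_atlas, make_synthetic_atlas, partition_edges,
)
from .connectome import (
    ConnectivityMatrix, FeatureMatrix, TimeSeriesPanel, bandpass_filter,
    build_feature_matrix, compute_fc, discard_initial_volumes,
)
from .predict import PredictionResult, RidgeConfig, nested_loocv
from .selection import (
    ForestConfig, ImportanceTable, fit_forest, oob_importance, select_features,
    write_importance_table,
)
from .simulate import (
    CohortData, SubjectRecord, SyntheticConfig, generate_cohort,
    generate_null_cohort, load_cohort_table,
)

__all__ = [
    "GroupSpec",
    "RunConfig",
    "split_groups",
    "run_full_pipeline",
    "run_group_analysis",
    "report_top_connections",
    "ConfigError",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class GroupSpec:
    """How to split the cohort for the covariate analyses.

    Age: sort by (age, subject_id) and take the first ceil(n/2) subjects as
    the younger group. Sex: by label. Exclusions are removed first and are
    always explicit, never automatic.
    """

    covariate: Literal["age", "sex"]
    exclusions: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    atlas: str = "bundled"  # "bundled", "synthetic:<n-per-hemisphere>" or a path
    simulate: SyntheticConfig | None = None
    ts_dir: str | None = None
    cohort_table: str | None = None
    discard_volumes: int = 10
    bandpass: bool = True
    forest: ForestConfig = field(default_factory=ForestConfig)
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    networks: tuple[Network, ...] = NETWORKS
    selection_scope: Literal["per_fold", "global"] = "per_fold"
    group: GroupSpec | None = None
    top_k: int = 10
    seed: int = 0
    out_dir: str = "hemiconn_run"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        unknown = [n for n in self.networks if n not in NETWORKS]
        if unknown:
            raise ConfigError(f"unknown network(s) {unknown}; valid: {NETWORKS}")
        if self.simulate is None and (self.ts_dir is None or self.cohort_table is None):
            raise ConfigError(
                "either a simulate block or ts_dir + cohort_table is required"
            )

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            if "planted_edges" in sim:
                sim["planted_edges"] = tuple(
                    ((int(e[0]), int(e[1])), float(b)) for e, b in sim["planted_edges"]
                )
            kwargs["simulate"] = SyntheticConfig(**sim)
        if "forest" in kwargs:
            kwargs["forest"] = ForestConfig(**kwargs["forest"])
        if "ridge" in kwargs:
            r = dict(kwargs["ridge"])
            for key in ("alpha_grid", "max_iter_grid"):
                if key in r:
                    r[key] = tuple(r[key])
            kwargs["ridge"] = RidgeConfig(**r)
        if "group" in kwargs and kwargs["group"] is not None:
            g = dict(kwargs["group"])
            if "exclusions" in g:
                g["exclusions"] = tuple(g["exclusions"])
            kwargs["group"] = GroupSpec(**g)
        if "networks" in kwargs:
            kwargs["networks"] = tuple(kwargs["networks"])
        try:
            return RunConfig(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _resolve_atlas(spec: str) -> Atlas:
    if spec == "bundled":
        return load_bundled_atlas()
    if spec.startswith("synthetic:"):
        return make_synthetic_atlas(int(spec.split(":", 1)[1]))
    p = Path(spec)
    if not p.exists():
        raise ConfigError(f"atlas path does not exist: {spec}")
    return load_atlas(p)


def _load_panels(config: RunConfig, atlas: Atlas) -> CohortData:
    records = load_cohort_table(config.cohort_table)
    panels = []
    for rec in records:
        path = Path(config.ts_dir) / f"{rec.subject_id}.tsv"
        if not path.exists():
            raise ConfigError(f"missing time-series file {path}")
        values = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
        if values.shape[1] != atlas.n_nodes:
            raise ConfigError(
                f"{path}: {values.shape[1]} ROI columns, atlas has {atlas.n_nodes}"
            )
        panel = TimeSeriesPanel(rec.subject_id, values, tr_seconds=2.0)
        if config.discard_volumes:
            panel = discard_initial_volumes(panel, config.discard_volumes)
        if config.bandpass:
            panel = bandpass_filter(panel)
        panels.append(panel)
    return CohortData(panels=panels, records=records, truth={})


def _obtain_cohort(config: RunConfig, atlas: Atlas) -> CohortData:
    if config.simulate is not None:
        # simulated panels already emulate post-discard, band-limited data
        return generate_cohort(config.simulate, atlas)
    return _load_panels(config, atlas)


def _derived_seed(base: int, *salt: int) -> int:
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def split_groups(
    subjects: Sequence[SubjectRecord], spec: GroupSpec
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition the cohort by the covariate; see :class:`GroupSpec`."""
    kept = [s for s in subjects if s.subject_id not in set(spec.exclusions)]
    if spec.covariate == "age":
        ordered = sorted(kept, key=lambda s: (s.age, s.subject_id))
        cut = (len(ordered) + 1) // 2
        first, second = ordered[:cut], ordered[cut:]
    elif spec.covariate == "sex":
        first = [s for s in kept if s.sex == "M"]
        second = [s for s in kept if s.sex == "F"]
    else:
        raise ConfigError(f"unknown covariate {spec.covariate!r}")
    for name, grp in (("first", first), ("second", second)):
        if len(grp) < 3:
            raise ValueError(
                f"{name} {spec.covariate} group has only {len(grp)} subjects (< 3)"
            )
        if len(grp) < 10:
            warnings.warn(
                f"{name} {spec.covariate} group has {len(grp)} subjects; "
                "LOOCV estimates will be unstable"
            )
    return first, second


def report_top_connections(
    importances: ImportanceTable, atlas: Atlas, k: int = 10
) -> pd.DataFrame:
    """Rank the top-k edges and express each as a gyrus-pair row.

    The "normalized connection value" column maps rank 1..m to
    ``(m - rank + 1) / m`` (1.0, 0.9, ..., 0.1 for a full top-10); when fewer
    than k edges are available all are reported and the values renormalize
    over the actual count, with a warning.
    """
    if importances.edges is None or len(importances.importance) == 0:
        raise ValueError("importance table is empty or carries no edges")
    d = len(importances.importance)
    m = min(k, d)
    if m < k:
        warnings.warn(f"only {m} features available for a top-{k} report")
    order = sorted(range(d), key=lambda q: (-importances.importance[q],
                                            importances.edges[q]))[:m]
    rows = []
    for rank, q in enumerate(order, start=1):
        i, j = importances.edges[q]
        ni, nj = atlas.node(i), atlas.node(j)
        rows.append({
            "rank": rank,
            "i": i, "j": j,
            "abbrev_i": ni.abbrev, "abbrev_j": nj.abbrev,
            "gyrus_i": ni.gyrus_id, "gyrus_j": nj.gyrus_id,
            "gyrus_name_i": GYRUS_NAMES.get(ni.gyrus_id, f"gyrus-{ni.gyrus_id}"),
            "gyrus_name_j": GYRUS_NAMES.get(nj.gyrus_id, f"gyrus-{nj.gyrus_id}"),
            "gyrus_abbrev_i": GYRUS_ABBREVS.get(ni.gyrus_id, f"G{ni.gyrus_id}"),
            "gyrus_abbrev_j": GYRUS_ABBREVS.get(nj.gyrus_id, f"G{nj.gyrus_id}"),
            "lobe_i": LOBE_NAMES.get(ni.lobe_id, f"lobe-{ni.lobe_id}"),
            "lobe_j": LOBE_NAMES.get(nj.lobe_id, f"lobe-{nj.lobe_id}"),
            "importance": float(importances.importance[q]),
            "normalized_value": (m - rank + 1) / m,
        })
    return pd.DataFrame(rows)


def _network_features(
    cohort: CohortData, atlas: Atlas, networks: Sequence[Network]
) -> dict[Network, FeatureMatrix]:
    fcs = [compute_fc(p, roi_names=atlas.abbrevs) for p in cohort.panels]
    partition = partition_edges(atlas)
    return {net: build_feature_matrix(fcs, partition, net) for net in networks}


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write a self-describing run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": _jsonable(config),
        "seed": config.seed,
        "files": {},
        "complete": False,
    }
    manifest_path = out / "manifest.json"
    try:
        logger.info("stage atlas: resolving %r", config.atlas)
        atlas = _resolve_atlas(config.atlas)
        logger.info("stage cohort: obtaining subjects")
        cohort = _obtain_cohort(config, atlas)
        y = [r.improvement_rate for r in cohort.records]
        logger.info("stage connectome: %d subjects, %d ROIs",
                    len(cohort.panels), atlas.n_nodes)
        feats = _network_features(cohort, atlas, config.networks)
        cohort_df = pd.DataFrame([vars(r) for r in cohort.records])
        cohort_df.to_csv(out / "cohort.tsv", sep="\t", index=False)
        for q, net in enumerate(config.networks):
            fm = feats[net]
            net_seed = _derived_seed(config.seed, 101, q)
            fcfg = replace(config.forest, seed=net_seed)
            rcfg = replace(config.ridge, seed=_derived_seed(config.seed, 103, q))
            logger.info("stage select/predict [%s]: %d edges, seed %d",
                        net, len(fm.edge_index), net_seed)
            # cohort-level importance table for reporting (Table-1-style)
            model = fit_forest(fm.values, y, fcfg)
            table = oob_importance(model, fm.values, y, edges=fm.edge_index,
                                   network=net)
            write_importance_table(table, out / f"importance_{net}.tsv")
            result = nested_loocv(fm, cohort.records, fcfg, rcfg,
                                  selection_scope=config.selection_scope)
            result.to_frame().to_csv(out / f"predictions_{net}.tsv",
                                     sep="\t", index=False)
            (out / f"summary_{net}.json").write_text(
                json.dumps(_jsonable(result.summary()), indent=1)
            )
            report = report_top_connections(table, atlas, k=config.top_k)
            report.to_csv(out / f"top{config.top_k}_{net}.tsv",
                          sep="\t", index=False)
            logger.info("[%s] r=%.3f p=%.3g R2=%.3f", net, result.pearson_r,
                        result.pearson_p, result.r_squared)
        if config.group is not None:
            group_results = run_group_analysis(config, config.group,
                                               cohort=cohort, atlas=atlas)
            (out / "group_summary.json").write_text(
                json.dumps(_jsonable(group_results), indent=1)
            )
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["files"] = {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.is_file() and p != manifest_path
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    manifest["complete"] = True
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.is_file() and p != manifest_path
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


def run_group_analysis(
    config: RunConfig,
    spec: GroupSpec,
    cohort: CohortData | None = None,
    atlas: Atlas | None = None,
) -> dict:
    """Inter-group screening, per-group nested-LOOCV evaluation.

    Feature screening runs once on the full (non-excluded) cohort per
    network; each covariate group is then evaluated by nested LOOCV on that
    shared edge set.
    """
    if atlas is None:
        atlas = _resolve_atlas(config.atlas)
    if cohort is None:
        cohort = _obtain_cohort(config, atlas)
    first, second = split_groups(cohort.records, spec)
    keep_ids = {s.subject_id for s in first} | {s.subject_id for s in second}
    keep_idx = [k for k, p in enumerate(cohort.panels) if p.subject_id in keep_ids]
    sub = CohortData(
        panels=[cohort.panels[k] for k in keep_idx],
        records=[r for r in cohort.records if r.subject_id in keep_ids],
        truth=cohort.truth,
    )
    feats = _network_features(sub, atlas, config.networks)
    y = np.array([r.improvement_rate for r in sub.records])
    results: dict = {"covariate": spec.covariate, "groups": {}}
    group_sets = {"first": first, "second": second}
    for q, net in enumerate(config.networks):
        fm = feats[net]
        fcfg = replace(config.forest, seed=_derived_seed(config.seed, 201, q))
        rcfg = replace(config.ridge, seed=_derived_seed(config.seed, 203, q))
        model = fit_forest(fm.values, y, fcfg)
        table = oob_importance(model, fm.values, y, edges=fm.edge_index, network=net)
        cols = select_features(table)
        edges = [fm.edge_index[c] for c in cols]
        for gname, grp in group_sets.items():
            gids = {s.subject_id for s in grp}
            rows = [k for k, sid in enumerate(fm.subjects) if sid in gids]
            gfm = FeatureMatrix(
                network=net,
                subjects=tuple(fm.subjects[k] for k in rows),
                edge_index=fm.edge_index,
                values=fm.values[rows],
            )
            res = nested_loocv(gfm, grp, fcfg, rcfg, preselected=edges)
            results["groups"].setdefault(gname, {})[net] = res.summary()
    return results
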