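"""End-to-end analysis: simulate, connect, map, infer, standardize, relate.

``run_pipeline`` executes eleven stages in order on one configuration:

1.  ``simulate``        synthetic cohort (atlas, time series, morphometry)
2.  ``sfc_maps``        per-subject connectome + SFC maps for three seeds
3.  ``young_average``   young-group mean SFC maps
4.  ``group_contrasts`` whole-caudate SFC group GLMs with permutation FWE
5.  ``paired_contrast`` medial-vs-lateral paired contrast (young), per step
6.  ``region_sets``     MCR / LCR / rest derived from the step-1 paired map
7.  ``normative``       z-standardization against young norms
8.  ``anova``           region-set ANOVA of standardized thickness
9.  ``combined_map``    young-average combined (argmax-step) map per region
10. ``correlations``    regional SFC vs standardized grey matter (Pearson)
11. ``report``          human-readable markdown summary

The expensive stage (per-subject connectome + SFC maps) and the permutation
stages are cached as ``.npz`` files under ``<out_dir>/cache`` keyed by the
configuration content hash, so re-running a finished or interrupted analysis
resumes instead of recomputing.  All randomness derives from the
configuration seeds; two runs of the same configuration are bit-identical.

The medial- and lateral-seed maps are z-scored over a common analysis mask
that excludes the *whole* caudate, so their per-node values are directly
comparable in the paired contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import Cohort, CohortConfig, generate_cohort
from .connectome import correlation_matrix, threshold_graph
from .inference import (
    FWEResult,
    RegionSets,
    StatMap,
    derive_region_sets,
    grid_adjacency,
    paired_permutation_fwe,
    permutation_fwe,
    two_sample_design,
)
from .morphometry import (
    AnovaResult,
    CorrelationResult,
    StandardizedTable,
    normative_stats,
    regionset_anova,
    sfc_gm_correlation,
    standardize,
)
from .sfc import (
    SeedSet,
    SFCMapSet,
    combined_map,
    partition_caudate,
    region_reduce,
    sfc_maps,
    whole_caudate_seed,
    zscore_maps,
)

__all__ = ["RunConfig", "RunResult", "STAGES", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "sfc_maps",
    "young_average",
    "group_contrasts",
    "paired_contrast",
    "region_sets",
    "normative",
    "anova",
    "combined_map",
    "correlations",
    "report",
)

SEED_NAMES = ("whole", "medial", "lateral")
GROUP_PAIRS = (("young", "middle"), ("young", "elderly"), ("middle", "elderly"))
MAX_STEP = 4


@dataclass
class RunConfig:
    """Cohort generation plus every analysis switch of the pipeline."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_rule: str = "fdr_q"
    threshold_value: float = 0.05
    n_perm: int = 1000
    enhancer: str = "none"  # "none" (maxT) or "tfce"
    tfce_params: dict = field(default_factory=dict)
    alpha: float = 0.05
    connectivity: int = 6
    min_frac: float = 0.1
    anova_unit: str = "region"
    analysis_seed: int = 1000

    def __post_init__(self) -> None:
        if self.enhancer not in ("none", "tfce"):
            raise ValueError(f"unknown enhancer {self.enhancer!r}")
        if self.anova_unit not in ("region", "subject"):
            raise ValueError(f"unknown anova unit {self.anova_unit!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_jsonable()
        return d

    def content_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_jsonable(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
            d["cohort"] = CohortConfig.from_jsonable(d["cohort"])
        return cls(**d)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) run configuration file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path} must contain a mapping at top level")
    return RunConfig.from_jsonable(raw)


@dataclass
class RunResult:
    """Everything the pipeline computed, plus the stage-status manifest."""

    config: RunConfig
    out_dir: Path
    cohort: Cohort | None = None
    seeds: dict[str, SeedSet] | None = None
    maps: dict[str, np.ndarray] | None = None  # seed -> (n_subj, MAX_STEP, n_nodes)
    young_average: dict[str, SFCMapSet] | None = None
    group_contrasts: dict[tuple[str, str, int], FWEResult] | None = None
    paired_contrasts: dict[int, FWEResult] | None = None
    region_sets: RegionSets | None = None
    z_thickness: StandardizedTable | None = None
    z_volumes: StandardizedTable | None = None
    anova: dict[str, AnovaResult | str] | None = None
    combined: pd.Series | None = None
    correlations: dict[tuple[str, str], CorrelationResult | str] | None = None
    manifest: dict = field(default_factory=dict)
    report_text: str = ""


# ---------------------------------------------------------------------------
# cache helpers

def _cache_dir(out_dir: Path, config: RunConfig) -> Path:
    d = out_dir / "cache" / config.content_hash()
    d.mkdir(parents=True, exist_ok=True)
    return d


def _save_fwe(path: Path, results: dict, key_fmt) -> None:
    arrays = {}
    meta = {}
    for key, res in results.items():
        tag = key_fmt(key)
        arrays[f"{tag}__p"] = res.p_corrected
        arrays[f"{tag}__mask"] = res.mask
        arrays[f"{tag}__t"] = res.tmap.t
        meta[tag] = {
            "df": res.tmap.df,
            "method": res.method,
            "n_permutations": res.n_permutations,
            "alpha": res.alpha,
        }
    np.savez_compressed(path, **arrays, __meta__=json.dumps(meta))


def _load_fwe(path: Path, keys, key_fmt) -> dict:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        out = {}
        for key in keys:
            tag = key_fmt(key)
            m = meta[tag]
            out[key] = FWEResult(
                z[f"{tag}__p"],
                z[f"{tag}__mask"],
                StatMap(z[f"{tag}__t"], int(m["df"])),
                m["method"],
                int(m["n_permutations"]),
                float(m["alpha"]),
            )
    return out


# ---------------------------------------------------------------------------
# stages

def _stage_sfc_maps(result: RunResult, cache: Path) -> None:
    cfg = result.config
    cohort = result.cohort
    atlas = cohort.atlas
    nt = cohort.node_table
    medial, lateral = partition_caudate(atlas, cfg.connectivity, nt)
    whole = whole_caudate_seed(atlas, nt)
    result.seeds = {"whole": whole, "medial": medial, "lateral": lateral}
    # common analysis mask for the medial/lateral pair: exclude the whole caudate
    caud_mask = np.ones(nt.n_nodes, dtype=bool)
    caud_mask[whole.nodes] = False

    path = cache / "sfc_maps.npz"
    if path.exists():
        with np.load(path) as z:
            result.maps = {name: z[name] for name in SEED_NAMES}
        return
    n_subj = len(cohort.subjects)
    maps = {name: np.empty((n_subj, MAX_STEP, nt.n_nodes)) for name in SEED_NAMES}
    for i, subj in enumerate(cohort.subjects):
        assoc = correlation_matrix(subj.timeseries)
        graph = threshold_graph(assoc, cfg.threshold_rule, cfg.threshold_value, nt)
        for name, seed in result.seeds.items():
            raw = sfc_maps(graph, seed, MAX_STEP)
            mask = None if name == "whole" else caud_mask
            z = zscore_maps(raw, mask)
            maps[name][i] = z.as_matrix()
    np.savez_compressed(path, **maps)
    result.maps = maps


def _stage_young_average(result: RunResult) -> None:
    cohort = result.cohort
    young_idx = [i for i, s in enumerate(cohort.subjects) if s.record.group == "young"]
    result.young_average = {}
    for name in SEED_NAMES:
        mean = result.maps[name][young_idx].mean(axis=0)
        steps = {k + 1: mean[k] for k in range(MAX_STEP)}
        result.young_average[name] = SFCMapSet(steps, result.seeds[name], "zscore")


def _stage_group_contrasts(result: RunResult, cache: Path, adjacency) -> None:
    cfg = result.config
    cohort = result.cohort
    keys = [(a, b, k) for a, b in GROUP_PAIRS for k in range(1, MAX_STEP + 1)]
    fmt = lambda key: f"{key[0]}_vs_{key[1]}_step{key[2]}"  # noqa: E731
    path = cache / "group_contrasts.npz"
    if path.exists():
        result.group_contrasts = _load_fwe(path, keys, fmt)
        return
    idx_of = {g: [i for i, s in enumerate(cohort.subjects) if s.record.group == g]
              for g in ("young", "middle", "elderly")}
    out = {}
    for pair_i, (a, b) in enumerate(GROUP_PAIRS):
        idx = idx_of[a] + idx_of[b]
        records = [cohort.subjects[i].record for i in idx]
        design, contrast = two_sample_design(records, a, b)
        for k in range(1, MAX_STEP + 1):
            Y = result.maps["whole"][idx, k - 1, :]
            rng = np.random.default_rng([cfg.analysis_seed, 10 + pair_i, k])
            out[(a, b, k)] = permutation_fwe(
                Y, design, contrast,
                n_perm=cfg.n_perm, enhancer=cfg.enhancer, alpha=cfg.alpha, rng=rng,
                adjacency=adjacency, tfce_params=cfg.tfce_params,
            )
    _save_fwe(path, out, fmt)
    result.group_contrasts = out


def _stage_paired_contrast(result: RunResult, cache: Path, adjacency) -> None:
    cfg = result.config
    cohort = result.cohort
    keys = list(range(1, MAX_STEP + 1))
    fmt = lambda k: f"step{k}"  # noqa: E731
    path = cache / "paired_contrast.npz"
    if path.exists():
        result.paired_contrasts = _load_fwe(path, keys, fmt)
        return
    young_idx = [i for i, s in enumerate(cohort.subjects) if s.record.group == "young"]
    out = {}
    for k in keys:
        A = result.maps["medial"][young_idx, k - 1, :]
        B = result.maps["lateral"][young_idx, k - 1, :]
        rng = np.random.default_rng([cfg.analysis_seed, 20, k])
        out[k] = paired_permutation_fwe(
            A, B, n_perm=cfg.n_perm, enhancer=cfg.enhancer, alpha=cfg.alpha, rng=rng,
            adjacency=adjacency, tfce_params=cfg.tfce_params,
        )
    _save_fwe(path, out, fmt)
    result.paired_contrasts = out


def _stage_normative(result: RunResult) -> None:
    cohort = result.cohort
    zt = {}
    for attr in ("thickness", "volumes"):
        table = getattr(cohort, attr)
        norms = normative_stats(table.subset("young"))
        older_subs = [s for s in table.subjects if s.group != "young"]
        older = type(table)(older_subs, table.values.loc[[s.id for s in older_subs]], table.measure_kind)
        zt[attr] = standardize(older, norms)
    result.z_thickness = zt["thickness"]
    result.z_volumes = zt["volumes"]


def _stage_anova(result: RunResult) -> None:
    cfg = result.config
    result.anova = {}
    for group in ("middle", "elderly"):
        try:
            result.anova[group] = regionset_anova(
                result.z_thickness, result.region_sets, group, cfg.anova_unit
            )
        except ValueError as exc:
            logger.warning("region-set ANOVA degenerate for %s: %s", group, exc)
            result.anova[group] = f"degenerate: {exc}"


def _stage_combined(result: RunResult) -> pd.Series:
    nt = result.cohort.node_table
    combined = combined_map(result.young_average["whole"])
    result.combined = region_reduce(combined.astype(float), nt)
    return result.combined


def _stage_correlations(result: RunResult) -> None:
    nt = result.cohort.node_table
    cortical = nt.atlas.labels_of_class("cortical_parcel")
    step1 = region_reduce(result.young_average["whole"].steps[1], nt, cortical)
    combined_vox = combined_map(result.young_average["whole"]).astype(float)
    combined_reg = region_reduce(combined_vox, nt, cortical)
    predictors = {"step1_strength": step1, "combined_step_index": combined_reg}
    result.correlations = {}
    for pname, series in predictors.items():
        for group in ("middle", "elderly"):
            try:
                result.correlations[(pname, group)] = sfc_gm_correlation(
                    series, result.z_thickness, pname, group
                )
            except ValueError as exc:
                logger.warning("correlation degenerate (%s, %s): %s", pname, group, exc)
                result.correlations[(pname, group)] = f"degenerate: {exc}"


# ---------------------------------------------------------------------------
# report

def _report(result: RunResult) -> str:
    cfg = result.config
    lines = [
        "# Caudate SFC aging analysis",
        "",
        f"Configuration hash: `{cfg.content_hash()}`  |  package version {_pkg_version}",
        "",
        "## Cohort",
        "",
    ]
    counts = {g: sum(1 for s in result.cohort.subjects if s.record.group == g)
              for g in ("young", "middle", "elderly")}
    lines.append(
        f"- subjects: {counts['young']} young / {counts['middle']} middle-aged / "
        f"{counts['elderly']} elderly; {result.cohort.node_table.n_nodes} graph nodes"
    )
    lines.append(
        f"- seeds: {len(result.seeds['medial'])} medial + "
        f"{len(result.seeds['lateral'])} lateral caudate voxels"
    )
    lines += ["", "## Group contrasts of whole-caudate SFC", ""]
    lines.append("| contrast | step | significant nodes | min corrected p |")
    lines.append("|---|---|---|---|")
    for (a, b, k), res in result.group_contrasts.items():
        pmin = np.nanmin(res.p_corrected) if np.isfinite(res.p_corrected).any() else np.nan
        lines.append(f"| {a} vs {b} | {k} | {int(res.mask.sum())} | {pmin:.4g} |")
    lines += ["", "## Medial vs lateral caudate (paired, young group)", ""]
    lines.append("| step | significant nodes | min corrected p |")
    lines.append("|---|---|---|")
    for k, res in result.paired_contrasts.items():
        pmin = np.nanmin(res.p_corrected) if np.isfinite(res.p_corrected).any() else np.nan
        lines.append(f"| {k} | {int(res.mask.sum())} | {pmin:.4g} |")
    rs = result.region_sets
    lines += [
        "",
        "## Region sets",
        "",
        f"- MCR ({len(rs.mcr)}): {', '.join(rs.mcr) or '(none)'}",
        f"- LCR ({len(rs.lcr)}): {', '.join(rs.lcr) or '(none)'}",
        f"- rest: {len(rs.rest)} regions",
        "",
        "## Region-set ANOVA of standardized thickness",
        "",
    ]
    for group, res in result.anova.items():
        if isinstance(res, str):
            lines.append(f"- {group}: {res}")
        else:
            lines.append(
                f"- {group}: F({res.df_between},{res.df_within}) = {res.F:.2f}, p = {res.p:.3g}; "
                + "; ".join(
                    f"{row['a']}-{row['b']} diff {row['diff']:+.2f} (p_adj {row['p_adj']:.3g})"
                    for _, row in res.posthoc.iterrows()
                )
            )
    lines += ["", "## SFC-morphometry correlations (across cortical regions)", ""]
    for (pname, group), res in result.correlations.items():
        if isinstance(res, str):
            lines.append(f"- {pname} vs {group} thickness Z: {res}")
        else:
            lines.append(
                f"- {pname} vs {group} thickness Z: r = {res.r:+.3f} (p = {res.p:.3g}, n = {res.n})"
            )
    lines.append("")
    return "\n".join(lines)


def _summary_numbers(result: RunResult) -> dict:
    out: dict = {"group_contrast_sig_nodes": {}, "paired_sig_nodes": {}}
    for (a, b, k), res in result.group_contrasts.items():
        out["group_contrast_sig_nodes"][f"{a}_vs_{b}_step{k}"] = int(res.mask.sum())
    for k, res in result.paired_contrasts.items():
        out["paired_sig_nodes"][f"step{k}"] = int(res.mask.sum())
    out["region_sets"] = result.region_sets.to_json()
    out["anova"] = {
        g: (r if isinstance(r, str) else {
            "F": r.F, "p": r.p, "set_means": r.set_means,
            "posthoc": {f"{row['a']}_vs_{row['b']}": row["p_adj"] for _, row in r.posthoc.iterrows()},
        })
        for g, r in result.anova.items()
    }
    out["correlations"] = {
        f"{p}__{g}": (r if isinstance(r, str) else {"r": r.r, "p": r.p, "n": r.n})
        for (p, g), r in result.correlations.items()
    }
    return out


# ---------------------------------------------------------------------------
# driver

def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    through: str | None = None,
) -> RunResult:
    """Run the analysis stages in order, caching the expensive ones.

    ``through`` stops after the named stage (inclusive); the default runs all
    eleven.  Outputs land in ``out_dir``: ``manifest.json``, ``results.json``,
    ``report.md``, ``region_sets.json``, ``combined_regional.tsv`` and the
    ``cache/`` directory.
    """
    if through is not None and through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {list(STAGES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = _cache_dir(out_dir, config)
    result = RunResult(config, out_dir)
    statuses: dict[str, str] = {}
    last = STAGES.index(through) if through else len(STAGES) - 1

    adjacency = None
    for stage_i, stage in enumerate(STAGES):
        if stage_i > last:
            statuses[stage] = "skipped"
            continue
        if stage == "simulate":
            result.cohort = generate_cohort(config.cohort)
        elif stage == "sfc_maps":
            _stage_sfc_maps(result, cache)
        elif stage == "young_average":
            _stage_young_average(result)
        elif stage == "group_contrasts":
            if config.enhancer == "tfce" and adjacency is None:
                adjacency = grid_adjacency(result.cohort.node_table, config.connectivity)
            _stage_group_contrasts(result, cache, adjacency)
        elif stage == "paired_contrast":
            if config.enhancer == "tfce" and adjacency is None:
                adjacency = grid_adjacency(result.cohort.node_table, config.connectivity)
            _stage_paired_contrast(result, cache, adjacency)
        elif stage == "region_sets":
            result.region_sets = derive_region_sets(
                result.paired_contrasts[1], result.cohort.node_table, min_frac=config.min_frac
            )
            (out_dir / "region_sets.json").write_text(
                json.dumps(result.region_sets.to_json(), indent=1)
            )
        elif stage == "normative":
            _stage_normative(result)
        elif stage == "anova":
            _stage_anova(result)
        elif stage == "combined_map":
            series = _stage_combined(result)
            series.to_csv(out_dir / "combined_regional.tsv", sep="\t", header=True)
        elif stage == "correlations":
            _stage_correlations(result)
        elif stage == "report":
            result.report_text = _report(result)
            (out_dir / "report.md").write_text(result.report_text)
            (out_dir / "results.json").write_text(
                json.dumps(_summary_numbers(result), indent=1, sort_keys=True)
            )
        statuses[stage] = "ok"
        logger.info("stage %s: %s", stage, statuses[stage])

    result.manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.content_hash(),
        "package_version": _pkg_version,
        "stages": [{"name": s, "status": statuses[s]} for s in STAGES],
    }
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
    return result
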