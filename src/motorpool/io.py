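"""Trace CSV dialect, run manifests and the simulate→align→scatter→analyze pipeline.

Trace dialect (one file per animal, UTF-8, comma-separated, ``.``
decimal, header row required)::

    section_index,z_um,record_type,x,y,pool_label,order_index

``record_type`` is one of ``neuron``, ``lateral_edge``, ``central_canal``,
``optical_ref``, ``axis``.  Neurons carry ``pool_label`` (dorsal/ventral);
landmarks carry ``order_index``.  Every section must have exactly 5
``lateral_edge`` and 4 ``optical_ref`` records and exactly one
``central_canal`` and one ``axis`` record (the axis row stores the unit
vector components in x, y).  A JSON sidecar ``<stem>.meta.json`` holds
animal_id, genotype, housing, age_weeks and seed provenance.  Unknown
extra columns are accepted with a warning (forward compatibility).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .types import POOL_LABELS, SectionTrace, SeriesTrace

logger = logging.getLogger(__name__)

RECORD_TYPES = ("neuron", "lateral_edge", "central_canal", "optical_ref", "axis")
_COLUMNS = ["section_index", "z_um", "record_type", "x", "y", "pool_label", "order_index"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix == ".csv" else Path(
        str(path) + ".meta.json"
    )


def write_series(series: SeriesTrace, path) -> Path:
    """Write a SeriesTrace in the trace CSV dialect plus its JSON sidecar."""
    path = Path(path)
    rows = []
    for sec in series.sections:
        base = dict(section_index=sec.section_index, z_um=sec.z_um)
        for (x, y), pool in zip(sec.neurons, sec.neuron_pools):
            rows.append({**base, "record_type": "neuron", "x": x, "y": y,
                         "pool_label": pool, "order_index": ""})
        for i, (x, y) in enumerate(sec.lateral_edge):
            rows.append({**base, "record_type": "lateral_edge", "x": x, "y": y,
                         "pool_label": "", "order_index": i})
        rows.append({**base, "record_type": "central_canal",
                     "x": sec.central_canal[0], "y": sec.central_canal[1],
                     "pool_label": "", "order_index": ""})
        rows.append({**base, "record_type": "axis",
                     "x": sec.midsagittal_axis[0], "y": sec.midsagittal_axis[1],
                     "pool_label": "", "order_index": ""})
        for i, (x, y) in enumerate(sec.optical_refs):
            rows.append({**base, "record_type": "optical_ref", "x": x, "y": y,
                         "pool_label": "", "order_index": i})
    df = pd.DataFrame(rows, columns=_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = dict(
        animal_id=series.animal_id,
        genotype=series.genotype,
        housing=series.housing,
        age_weeks=series.age_weeks,
        provenance=series.provenance,
        seed=series.meta.get("seed"),
    )
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_series(path) -> SeriesTrace:
    """Read and validate a trace CSV file (with its JSON sidecar)."""
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"trace file not found: {path}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TraceFormatError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())

    df = pd.read_csv(path, dtype={"pool_label": "string"}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")

    # line numbers: header is line 1, first data row line 2
    def line(i):
        return int(i) + 2

    bad_type = df[~df["record_type"].isin(RECORD_TYPES)]
    if len(bad_type):
        i = bad_type.index[0]
        raise TraceFormatError(
            f"{path}:{line(i)}: unknown record_type {bad_type['record_type'].iloc[0]!r}"
        )
    for col in ("x", "y", "z_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = vals.index[vals.isna()][0]
            raise TraceFormatError(f"{path}:{line(i)}: non-numeric {col}")
        if not np.isfinite(vals).all():
            i = vals.index[~np.isfinite(vals)][0]
            raise TraceFormatError(f"{path}:{line(i)}: non-finite {col}")

    file_order = df["section_index"].drop_duplicates().tolist()
    if any(b <= a for a, b in zip(file_order, file_order[1:])):
        raise TraceFormatError(f"{path}: section_index not strictly increasing")

    sections = []
    seen = []
    for idx, sub in df.groupby("section_index", sort=True):
        counts = sub["record_type"].value_counts()
        for rt, expected in (("lateral_edge", 5), ("optical_ref", 4),
                             ("central_canal", 1), ("axis", 1)):
            got = int(counts.get(rt, 0))
            if got != expected:
                raise TraceFormatError(
                    f"{path}: section {idx}: expected {expected} {rt} "
                    f"record(s), found {got}"
                )
        neurons = sub[sub["record_type"] == "neuron"]
        bad_pool = neurons[~neurons["pool_label"].isin(POOL_LABELS)]
        if len(bad_pool):
            i = bad_pool.index[0]
            raise TraceFormatError(
                f"{path}:{line(i)}: neuron with invalid pool_label "
                f"{bad_pool['pool_label'].iloc[0]!r}"
            )
        edge = sub[sub["record_type"] == "lateral_edge"].sort_values("order_index")
        refs = sub[sub["record_type"] == "optical_ref"].sort_values("order_index")
        canal = sub[sub["record_type"] == "central_canal"].iloc[0]
        axis = sub[sub["record_type"] == "axis"].iloc[0]
        sections.append(
            SectionTrace(
                section_index=int(idx),
                z_um=float(sub["z_um"].iloc[0]),
                neurons=neurons[["x", "y"]].to_numpy(float),
                neuron_pools=neurons["pool_label"].to_numpy(object),
                lateral_edge=edge[["x", "y"]].to_numpy(float),
                central_canal=np.array([canal["x"], canal["y"]], float),
                midsagittal_axis=np.array([axis["x"], axis["y"]], float),
                optical_refs=refs[["x", "y"]].to_numpy(float),
            )
        )
        seen.append(int(idx))
    if any(b <= a for a, b in zip(seen, seen[1:])):
        raise TraceFormatError(f"{path}: section_index not strictly increasing")

    return SeriesTrace(
        animal_id=str(meta.get("animal_id", path.stem)),
        genotype=meta.get("genotype", "wt"),
        housing=meta.get("housing", "NH"),
        age_weeks=int(meta.get("age_weeks", 12)),
        sections=sections,
        provenance=meta.get("provenance", ""),
        meta={"seed": meta.get("seed")},
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "presets": ["NH/wt/12wk", "NH/mut/12wk"],
    "n_sections": 30,
    "neurons_per_pool": 60,
    "enlargement_amplitude": 0.3,
    "enlargement_width": 5.0,
    "rigid_jitter_translation": 0.05,
    "rigid_jitter_rotation": 0.05,
    "landmark_noise": 0.005,
    "report": "txt",
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        import yaml

        p = Path(path_or_dict)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def scatter_table(series_list) -> pd.DataFrame:
    """Align, normalize and project each series; one row per animal x pool."""
    from .geometry import normalize_sections, project_pool, rigid_align
    from .morphometry import scatter_index

    rows = []
    for series in series_list:
        aligned = normalize_sections(rigid_align(series))
        for pool in POOL_LABELS:
            ap = project_pool(aligned, pool)
            if ap.n_neurons < 3:
                logger.warning(
                    "%s %s pool has %d neurons; skipped", series.animal_id, pool,
                    ap.n_neurons,
                )
                continue
            res = scatter_index(ap)
            rows.append(
                dict(
                    animal_id=series.animal_id,
                    genotype=series.genotype,
                    housing=series.housing,
                    age_weeks=series.age_weeks,
                    pool=pool,
                    n_neurons=res.n_neurons,
                    sd_ml=res.sd_ml,
                    sd_dv=res.sd_dv,
                    si=res.si,
                )
            )
    return pd.DataFrame(rows)


def analyze_cohort(tables) -> tuple[pd.DataFrame, list]:
    """Run the standard comparison battery on cohort tables.

    Returns (results table, report lines).  Per housing x age x pool:
    wt-vs-mut comparisons of SI and directional SDs; per housing the
    genotype x time interaction of crossing time; synapse and PNN
    comparisons; and the SI-vs-performance regression over ventral pools.
    """
    from .stats import (
        category_distribution_compare,
        compare_groups,
        rm_anova_interaction,
        si_behavior_regression,
        synapse_compare,
    )

    rows, report = [], []
    scatter = tables.scatter

    def add(comparison_id, gc):
        rows.append(
            dict(
                comparison=comparison_id,
                groups=" vs ".join(s["name"] for s in gc.summaries[:2]),
                n=";".join(str(s["n"]) for s in gc.summaries),
                means=";".join(f"{s['mean']:.6g}" for s in gc.summaries),
                sems=";".join(f"{s['sem']:.6g}" for s in gc.summaries),
                test=gc.test_used,
                statistic=gc.statistic,
                p=gc.p,
            )
        )
        report.append(f"{comparison_id}: {gc.summary_line()}")

    for (housing, age, pool), sub in scatter.groupby(["housing", "age_weeks", "pool"]):
        wt = sub[sub["genotype"] == "wt"]
        mut = sub[sub["genotype"] == "mut"]
        if len(wt) < 3 or len(mut) < 3:
            continue
        for metric in ("si", "sd_ml", "sd_dv"):
            gc = compare_groups(
                wt[metric], mut[metric], names=("wt", "mut")
            )
            add(f"{housing}/{age}wk/{pool}/{metric}", gc)

    behavior = tables.behavior
    for housing, sub in behavior.groupby("housing"):
        if sub["genotype"].nunique() == 2:
            try:
                gc = rm_anova_interaction(sub)
                add(f"{housing}/crossing_time/genotype_x_time", gc)
            except Exception as exc:  # insufficient cells in tiny demos
                report.append(f"{housing}/crossing_time interaction skipped: {exc}")

    if len(tables.synapse):
        try:
            for key, gc in synapse_compare(tables.synapse).items():
                genotype, h1, h2, kind = key
                add(f"synapse/{genotype}/{h1}_vs_{h2}/{kind}", gc)
        except Exception as exc:
            report.append(f"synapse comparisons skipped: {exc}")

    if len(tables.pnn):
        try:
            for cat, gc in category_distribution_compare(tables.pnn).items():
                add(f"pnn/{cat}", gc)
        except Exception as exc:
            report.append(f"pnn comparisons skipped: {exc}")

    # SI vs 12-week crossing time over ventral pools, both genotypes pooled
    vent = scatter[scatter["pool"] == "ventral"]
    b12 = behavior[behavior["timepoint_weeks"] == 12][["animal_id", "crossing_time_s"]]
    merged = vent.merge(b12, on="animal_id")
    if len(merged) >= 3 and merged["crossing_time_s"].nunique() > 1:
        slope, se, p = si_behavior_regression(
            merged["si"], merged["crossing_time_s"]
        )
        rows.append(
            dict(
                comparison="ventral_si_vs_crossing_time",
                groups="all animals",
                n=str(len(merged)),
                means=f"{slope:.6g}",
                sems=f"{se:.6g}",
                test="ols",
                statistic=slope / se if se > 0 else float("nan"),
                p=p,
            )
        )
        report.append(
            f"ventral SI vs crossing time: slope = {slope:.4g} ± {se:.4g}, "
            f"p = {p:.4g}, N = {len(merged)}"
        )
    return pd.DataFrame(rows), report


def run_pipeline(config, seed: int | None = None, out=None) -> Path:
    """simulate → align → scatter → analyze → report, under a run directory.

    Writes trace CSVs, cohort tables, scatter results, an analysis table,
    a plain-text report and a manifest (config hash, seeds, version).
    """
    from . import __version__
    from .synth import SimConfig, gen_cohort, get_preset

    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out is not None:
        cfg["out"] = str(out)
    run_dir = Path(cfg.get("out", "motorpool_run"))
    run_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        presets = [get_preset(name) for name in cfg["presets"]]
        sim = SimConfig(
            seed=int(cfg["seed"]),
            n_sections=int(cfg["n_sections"]),
            neurons_per_pool=int(cfg["neurons_per_pool"]),
            enlargement_amplitude=float(cfg["enlargement_amplitude"]),
            enlargement_width=float(cfg["enlargement_width"]),
            rigid_jitter_translation=float(cfg["rigid_jitter_translation"]),
            rigid_jitter_rotation=float(cfg["rigid_jitter_rotation"]),
            landmark_noise=float(cfg["landmark_noise"]),
        )
        tables, series_list = gen_cohort(presets, seed=int(cfg["seed"]), config=sim)
        traces = run_dir / "traces"
        for s in series_list:
            write_series(s, traces / f"{s.animal_id}.csv")
        tables.write(run_dir / "cohort")

        stage = "align+scatter"
        measured = scatter_table(series_list)
        measured.to_csv(run_dir / "scatter_results.csv", index=False)

        stage = "analyze"
        pipeline_tables = type(tables)(
            behavior=tables.behavior,
            scatter=measured,
            synapse=tables.synapse,
            pnn=tables.pnn,
            truth=tables.truth,
        )
        results, report = analyze_cohort(pipeline_tables)
        results.to_csv(run_dir / "analysis_results.csv", index=False)

        stage = "report"
        (run_dir / "report.txt").write_text("\n".join(report) + "\n")
        manifest = dict(
            version=__version__,
            seed=int(cfg["seed"]),
            config=cfg,
            config_hash=_config_hash(cfg),
            n_series=len(series_list),
            stages=["simulate", "align+scatter", "analyze", "report"],
        )
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )
    except Exception:
        (run_dir / "FAILED_STAGE.txt").write_text(stage + "\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return run_dir
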