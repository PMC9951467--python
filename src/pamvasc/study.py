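"""Study-level orchestration: 4 groups x n subjects x 7 timepoints.

For each subject the pipeline runs surface detection -> flattening -> layer
segmentation at t=0 -> layer-wise MAPs -> averaged-Otsu series threshold ->
density and centroid traces; group summaries (mean +/- SEM of relative
density) and two-tailed paired t-tests on the final constriction percentages
produce the group-level analysis products: summary tables, significance tests and figures.

The paired test is applied between groups of different subjects matched by
index — the convention of the blanching-assay protocol this pipeline
implements; an unpaired Welch test is available via
``StudyConfig.test_kind = "welch"`` for users who prefer it between
independent groups.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .config import AnalysisConfig
from .layers import (LayerBoundaries, SegmentationError, depth_histogram,
                     find_layer_peaks, layer_map, segment_layers)
from .quantify import (CentroidTrace, DensityTrace, centroid_depth,
                       relative_trace, series_threshold, vascular_density)
from .surface import detect_surface, flatten
from .volume_io import LAYER_TAGS, PAVolume


class DegenerateTestError(ValueError):
    """Raised when a paired test has zero difference variance."""


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Pointwise mean and SEM of relative density for one group x layer."""

    group: str
    layer_tag: str
    t_min: list[float]
    mean_relative: list[float]
    sem_relative: list[float]
    constriction_mean: float
    constriction_sem: float
    n: int


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def group_summary(traces: Sequence[DensityTrace]) -> GroupSummary:
    """Summarize one group's traces for one layer (mean +/- SEM; n >= 2)."""
    if len(traces) < 2:
        raise ValueError("group summary needs at least two subjects")
    t0 = traces[0].t_min
    for tr in traces[1:]:
        if tr.t_min != t0:
            raise ValueError(f"mismatched timepoint grids: {tr.t_min} vs {t0}")
        if tr.layer_tag != traces[0].layer_tag or tr.group != traces[0].group:
            raise ValueError("group_summary expects traces of one group and layer")
    rel = np.array([tr.relative for tr in traces])
    con = np.array([tr.constriction_pct for tr in traces])
    return GroupSummary(
        group=traces[0].group,
        layer_tag=traces[0].layer_tag,
        t_min=list(t0),
        mean_relative=rel.mean(axis=0).tolist(),
        sem_relative=[_sem(rel[:, k]) for k in range(rel.shape[1])],
        constriction_mean=float(con.mean()),
        constriction_sem=_sem(con),
        n=len(traces),
    )


@dataclass
class TestResult:
    label: str
    t_stat: float
    p_value: float
    n: int
    df: int
    band: str  # "p<0.005", "p<0.05", or "ns"


def _band(p: float) -> str:
    if p < 0.005:
        return "p<0.005"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def paired_ttest(a: Sequence[float], b: Sequence[float], label: str = "") -> TestResult:
    """Two-tailed paired t-test on index-matched values.

    ``t = mean(d) / (sd(d) / sqrt(n))`` on differences ``d = a - b`` with the
    n-1 sample standard deviation; p from the t distribution with n-1 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_ttest needs two equal-length vectors of n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired_ttest requires finite values")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateTestError("zero variance of paired differences")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult(label=label, t_stat=t, p_value=p, n=n, df=n - 1, band=_band(p))


def welch_ttest(a: Sequence[float], b: Sequence[float], label: str = "") -> TestResult:
    """Unpaired Welch t-test (offered as the defensible alternative between
    independent groups; not the default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = int(np.floor(res.df))
    return TestResult(label=label, t_stat=float(res.statistic), p_value=float(res.pvalue),
                      n=len(a), df=df, band=_band(float(res.pvalue)))


# ---------------------------------------------------------------------------
# per-subject pipeline
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    subject_id: str
    group: str
    boundaries: LayerBoundaries
    traces: dict[str, DensityTrace]
    centroid: CentroidTrace
    voxel_threshold: float


def analyze_subject(volumes: Iterable[PAVolume], config: AnalysisConfig | None = None) -> SubjectResult:
    """Run the full per-subject pipeline over one timepoint series.

    Volumes must arrive in time order starting at t=0 (layer boundaries and
    the centroid voxel threshold are fixed from the t=0 volume so that the
    constriction itself cannot shift the segmentation mid-series).
    """
    cfg = config or AnalysisConfig()
    boundaries: LayerBoundaries | None = None
    voxel_threshold = 0.0
    maps: dict[str, list] = {layer: [] for layer in LAYER_TAGS}
    centroids: list[float] = []
    t_grid: list[float] = []
    subject_id = group = ""
    shape0 = None
    for vol in volumes:
        if shape0 is None:
            shape0 = vol.shape
            subject_id, group = vol.subject_id, vol.group
            if vol.t_min != 0.0:
                raise ValueError(f"series must start at t=0, got t={vol.t_min}")
        elif vol.shape != shape0:
            raise ValueError(f"mixed grid shapes: {vol.shape} vs {shape0}")
        elif t_grid and vol.t_min <= t_grid[-1]:
            raise ValueError("volumes must be in strictly increasing time order")
        if boundaries is None or not cfg.surface.fix_to_t0:
            surf = detect_surface(
                vol, cfg.surface.frac,
                noise_floor=cfg.surface.noise_floor,
                median_window=cfg.surface.median_window,
                reference_window=cfg.surface.reference_window,
                outlier_margin_um=cfg.surface.outlier_margin_um,
            )
        flat = flatten(vol, surf)
        if boundaries is None or not cfg.layers.fix_to_t0:
            hist = depth_histogram(flat, smooth_window_um=cfg.layers.smooth_window_um)
            peaks = find_layer_peaks(hist, min_separation_um=cfg.layers.min_separation_um)
            new_bounds = segment_layers(peaks, nz=vol.shape[2],
                                        rule=cfg.layers.boundary_rule, hist=hist)
            if boundaries is None:
                boundaries = new_bounds
                voxel_threshold = hist.voxel_threshold
            else:
                boundaries = new_bounds
        for layer in LAYER_TAGS:
            maps[layer].append(layer_map(flat, boundaries, layer))
        centroids.append(centroid_depth(flat, voxel_threshold,
                                        weighting=cfg.quantify.centroid_weighting))
        t_grid.append(vol.t_min)
    if shape0 is None:
        raise ValueError("empty volume series")
    traces = {}
    for layer in LAYER_TAGS:
        thr = series_threshold(maps[layer], n_bins=cfg.quantify.n_bins)
        densities = [vascular_density(m, thr) for m in maps[layer]]
        traces[layer] = relative_trace(subject_id, group, layer, t_grid, densities, thr)
    centroid = CentroidTrace(subject_id=subject_id, group=group, layer_tag="WHOLE",
                             t_min=t_grid, centroid_um=centroids)
    return SubjectResult(subject_id=subject_id, group=group, boundaries=boundaries,
                         traces=traces, centroid=centroid, voxel_threshold=voxel_threshold)


# ---------------------------------------------------------------------------
# study-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    traces: pd.DataFrame
    summaries: pd.DataFrame
    tests: pd.DataFrame
    centroids: pd.DataFrame
    boundaries: pd.DataFrame
    subject_results: list[SubjectResult]
    manifest: dict = field(default_factory=dict)

    def constriction(self, group: str, layer: str) -> np.ndarray:
        """Per-subject final-timepoint constriction percentages."""
        rows = self.traces[(self.traces.group == group) & (self.traces.layer == layer)]
        finals = rows[rows.t_min == rows.t_min.max()]
        return (100.0 * (1.0 - finals.relative)).to_numpy()

    def mean_constriction(self, group: str, layer: str) -> float:
        return float(self.constriction(group, layer).mean())

    def save(self, out_dir: str | Path, figures: bool = True) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(out / "traces.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.centroids.to_csv(out / "centroids.csv", index=False)
        self.boundaries.to_csv(out / "boundaries.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))
        if figures:
            save_figures(self, out / "figures")
        return out


def default_comparisons(groups: Sequence[str]) -> list[dict]:
    """Group-vs-control per layer, plus the within-group layer contrasts
    that distinguish the delivery routes."""
    comps: list[dict] = []
    if "control" in groups:
        for g in groups:
            if g == "control":
                continue
            for layer in LAYER_TAGS:
                comps.append({"kind": "group", "layer": layer, "a": g, "b": "control"})
    for g in ("injection", "topical"):
        if g in groups:
            comps.append({"kind": "layer", "group": g, "a": "PD", "b": "RD"})
            comps.append({"kind": "layer", "group": g, "a": "RD", "b": "HD"})
    return comps


def _config_hash(cfg: AnalysisConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def analyze_study(subject_streams: Iterable[tuple[str, str, Iterable[PAVolume]]],
                  config: AnalysisConfig | None = None) -> StudyResult:
    """Analyze a collection of subjects given as (group, subject_id, volumes).

    Subjects whose series is incomplete or fails segmentation are excluded
    from the statistics and listed in the manifest with the failure reason —
    never silently dropped.
    """
    cfg = config or AnalysisConfig()
    results: list[SubjectResult] = []
    excluded: list[dict] = []
    expected_t: list[float] | None = None
    for group, subject_id, volumes in subject_streams:
        try:
            res = analyze_subject(volumes, cfg)
            t_grid = res.traces["WHOLE"].t_min
            if expected_t is None:
                expected_t = t_grid
            elif t_grid != expected_t:
                raise ValueError(
                    f"incomplete series: timepoints {t_grid} != expected {expected_t}")
            results.append(res)
        except (SegmentationError, ValueError) as exc:
            excluded.append({"subject_id": subject_id, "group": group, "reason": str(exc)})

    trace_rows, centroid_rows, boundary_rows = [], [], []
    for res in results:
        for layer, tr in res.traces.items():
            for k, t in enumerate(tr.t_min):
                trace_rows.append({
                    "subject_id": tr.subject_id, "group": tr.group, "layer": layer,
                    "t_min": t, "density": tr.density[k], "relative": tr.relative[k],
                    "threshold": tr.threshold_used,
                })
        for k, t in enumerate(res.centroid.t_min):
            centroid_rows.append({
                "subject_id": res.subject_id, "group": res.group, "t_min": t,
                "centroid_um": res.centroid.centroid_um[k],
                "displacement_um": res.centroid.displacement_um[k],
            })
        b = res.boundaries
        boundary_rows.append({
            "subject_id": res.subject_id, "group": res.group, "d_pd": b.d_pd,
            "d_hd": b.d_hd, "z_pd_rd": b.z_pd_rd, "z_rd_hd": b.z_rd_hd, "rule": b.rule,
        })
    traces_df = pd.DataFrame(trace_rows, columns=[
        "subject_id", "group", "layer", "t_min", "density", "relative", "threshold"])
    centroids_df = pd.DataFrame(centroid_rows, columns=[
        "subject_id", "group", "t_min", "centroid_um", "displacement_um"])
    boundaries_df = pd.DataFrame(boundary_rows, columns=[
        "subject_id", "group", "d_pd", "d_hd", "z_pd_rd", "z_rd_hd", "rule"])

    summary_rows = []
    by_group_layer: dict[tuple[str, str], list[DensityTrace]] = {}
    for res in results:
        for layer, tr in res.traces.items():
            by_group_layer.setdefault((res.group, layer), []).append(tr)
    for (group, layer), trs in sorted(by_group_layer.items()):
        if len(trs) < 2:
            continue
        gs = group_summary(trs)
        for k, t in enumerate(gs.t_min):
            summary_rows.append({
                "group": group, "layer": layer, "t_min": t,
                "mean_relative": gs.mean_relative[k], "sem_relative": gs.sem_relative[k],
                "constriction_mean_pct": gs.constriction_mean,
                "constriction_sem_pct": gs.constriction_sem, "n": gs.n,
            })
    summaries_df = pd.DataFrame(summary_rows, columns=[
        "group", "layer", "t_min", "mean_relative", "sem_relative",
        "constriction_mean_pct", "constriction_sem_pct", "n"])

    groups_present = sorted({res.group for res in results})
    comps = cfg.study.comparisons or default_comparisons(groups_present)
    test_fn = paired_ttest if cfg.study.test_kind == "paired" else welch_ttest
    test_rows = []

    def _finals(group: str, layer: str) -> np.ndarray:
        vals = [100.0 * (1.0 - res.traces[layer].relative[-1])
                for res in results if res.group == group]
        return np.asarray(vals)

    for comp in comps:
        try:
            if comp["kind"] == "group":
                a = _finals(comp["a"], comp["layer"])
                b = _finals(comp["b"], comp["layer"])
                label = f"{comp['layer']}: {comp['a']} vs {comp['b']}"
            else:
                a = _finals(comp["group"], comp["a"])
                b = _finals(comp["group"], comp["b"])
                label = f"{comp['group']}: {comp['a']} vs {comp['b']}"
            if len(a) < 2 or len(a) != len(b):
                continue
            tr = test_fn(a, b, label=label)
            p = tr.p_value
            if cfg.study.bonferroni:
                p = min(1.0, p * len(comps))
            test_rows.append({"comparison": tr.label, "t": tr.t_stat, "p": p,
                              "n": tr.n, "df": tr.df, "band": _band(p)})
        except DegenerateTestError as exc:
            test_rows.append({"comparison": label, "t": np.nan, "p": np.nan,
                              "n": len(a), "df": len(a) - 1, "band": f"degenerate: {exc}"})
    tests_df = pd.DataFrame(test_rows, columns=["comparison", "t", "p", "n", "df", "band"])

    manifest = {
        "pamvasc_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_subjects_analyzed": len(results),
        "n_per_group": {g: sum(r.group == g for r in results) for g in groups_present},
        "timepoints_min": expected_t,
        "excluded_subjects": excluded,
    }
    return StudyResult(traces=traces_df, summaries=summaries_df, tests=tests_df,
                       centroids=centroids_df, boundaries=boundaries_df,
                       subject_results=results, manifest=manifest)


def run_phantom_study(spec=None, groups=None, n_subjects: int = 6,
                      config: AnalysisConfig | None = None):
    """Generate a phantom study and push it through the full pipeline.

    Returns ``(StudyResult, StudyBundle)``; the bundle carries each subject's
    :class:`~pamvasc.phantom.GroundTruth` for oracle comparisons.  Volumes
    are rendered lazily, one subject at a time.
    """
    from .phantom import PhantomSpec, generate_study

    spec = spec or PhantomSpec.default()
    bundle = generate_study(spec, groups=groups, n_subjects=n_subjects)
    streams = ((s.group, s.subject_id, s.volumes()) for s in bundle.subjects)
    result = analyze_study(streams, config)
    result.manifest["phantom_master_seed"] = spec.seed
    result.manifest["phantom_grid"] = list(spec.shape)
    return result, bundle


def run_pipeline(data_dir: str | Path, out_dir: str | Path | None = None,
                 config: AnalysisConfig | None = None) -> StudyResult:
    """Analyze a directory of volume files (TIFF/HDF5 written by this
    package) grouped by their subject metadata; optionally save all outputs."""
    from .volume_io import read_volume, read_volume_meta

    data_dir = Path(data_dir)
    files = sorted(list(data_dir.glob("*.h5")) + list(data_dir.glob("*.hdf5"))
                   + list(data_dir.glob("*.tif")) + list(data_dir.glob("*.tiff")))
    if not files:
        raise FileNotFoundError(f"no volume files in {data_dir}")
    by_subject: dict[tuple[str, str], list[Path]] = {}
    for f in files:
        meta = read_volume_meta(f)
        by_subject.setdefault((meta["group"], meta["subject_id"]), []).append(f)

    def stream(paths: list[Path]):
        vols = sorted((read_volume(p) for p in paths), key=lambda v: v.t_min)
        yield from vols

    streams = ((group, sid, stream(paths))
               for (group, sid), paths in sorted(by_subject.items()))
    result = analyze_study(streams, config)
    if out_dir is not None:
        result.save(out_dir)
    return result


def save_figures(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Density-vs-time panels per layer (mean +/- SEM per group) and the
    centroid-displacement panel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    colors = {"injection": "tab:red", "topical": "tab:blue",
              "nonsteroid": "tab:green", "control": "black"}
    for layer in LAYER_TAGS:
        sub = result.summaries[result.summaries.layer == layer]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for group, gdf in sub.groupby("group"):
            gdf = gdf.sort_values("t_min")
            ax.errorbar(gdf.t_min, gdf.mean_relative, yerr=gdf.sem_relative,
                        label=group, color=colors.get(group), capsize=3, marker="o")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("relative vascular density")
        ax.set_title(f"{layer} layer")
        ax.legend(fontsize=8)
        p = out / f"density_{layer}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    if not result.centroids.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        agg = result.centroids.groupby(["group", "t_min"]).displacement_um.mean().reset_index()
        for group, gdf in agg.groupby("group"):
            ax.plot(gdf.t_min, gdf.displacement_um, marker="o",
                    label=group, color=colors.get(group))
        ax.set_xlabel("time (min)")
        ax.set_ylabel("centroid displacement (um, + = deeper)")
        ax.legend(fontsize=8)
        p = out / "centroid_displacement.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths
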