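"""End-to-end orchestration and command-line interface.

Runs the three prediction workflows on a cohort directory (phantom or
real-format NIfTI + CSV):

* WF1 — 56 radiomic features → PCA (6 components) → 7 regression models;
* WF2 — 56 radiomic features → information-imbalance subset per target →
  7 models;
* WF3 — healthy-control reference limits → FFG/MEG single covariates →
  7 models;

all under seeded 5-fold cross-validation with identical fold assignments
across workflows, so workflow comparisons are paired rather than fold
noise. Outputs are per-workflow MAE tables (rows muscles, columns
models, cells "mean (sd)"), a muscle-wise coefficient-of-variation table
for ground-truth FF, wT2 and muscle volume, and a correlation screen
between the KNN mean MAE and those variability measures.
"""
from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import phantoms, preprocess, radiomics, reduce, regress, wf3 as wf3mod
from .phantoms import MUSCLES, PhantomParams, Subject
from .regress import MODEL_NAMES, CvResult, ModelSpec

logger = logging.getLogger(__name__)

TARGETS = ("FF", "wT2")
TARGET_COLUMN = {"FF": "FF_pp", "wT2": "wT2_ms"}


@dataclass
class RunConfig:
    fshd_dir: str | None = None
    hc_dir: str | None = None
    workflows: tuple[int, ...] = (1, 2, 3)
    targets: tuple[str, ...] = TARGETS
    seed: int = 0
    output_dir: str = "results"
    normalize: bool = True                  # histogram-match to HC reference
    n_quantiles: int = 256
    n_levels: int = radiomics.DEFAULT_GRAY_LEVELS
    pca_components: int = 6
    imbalance_max_size: int = 8
    fit_scope: str = "fold"                 # "fold" | "global"
    wf3_bin_width: float = 1.0
    wf3_pooling: str = "pooled"
    cv_folds: int = 5

    def validate(self) -> None:
        if not set(self.workflows) <= {1, 2, 3}:
            raise ValueError("workflows must be a subset of {1, 2, 3}")
        if not set(self.targets) <= set(TARGETS):
            raise ValueError(f"targets must be a subset of {TARGETS}")
        if 3 in self.workflows and self.hc_dir is None:
            raise ValueError("workflow 3 requires an HC cohort (hc_dir)")
        if self.fit_scope not in ("fold", "global"):
            raise ValueError("fit_scope must be 'fold' or 'global'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        cohorts = raw.get("cohorts", {})
        cfg.fshd_dir = cohorts.get("fshd", cfg.fshd_dir)
        cfg.hc_dir = cohorts.get("hc", cfg.hc_dir)
        cfg.workflows = tuple(raw.get("workflows", cfg.workflows))
        cfg.targets = tuple(raw.get("targets", cfg.targets))
        cfg.seed = raw.get("seed", cfg.seed)
        cfg.output_dir = raw.get("output_dir", cfg.output_dir)
        pre = raw.get("preprocess", {})
        cfg.normalize = pre.get("enabled", cfg.normalize)
        cfg.n_quantiles = pre.get("n_quantiles", cfg.n_quantiles)
        cfg.n_levels = raw.get("radiomics", {}).get("n_levels", cfg.n_levels)
        red = raw.get("reduce", {})
        cfg.pca_components = red.get("n_components", cfg.pca_components)
        cfg.imbalance_max_size = red.get("max_subset_size",
                                         cfg.imbalance_max_size)
        cfg.fit_scope = red.get("fit_scope", cfg.fit_scope)
        w3 = raw.get("wf3", {})
        cfg.wf3_bin_width = w3.get("bin_width", cfg.wf3_bin_width)
        cfg.wf3_pooling = w3.get("pooling", cfg.wf3_pooling)
        cfg.cv_folds = raw.get("regress", {}).get("k", cfg.cv_folds)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    #: workflow -> target -> muscle -> model -> CvResult
    results: dict[int, dict[str, dict[str, dict[str, CvResult]]]]
    cv_table: pd.DataFrame                  # muscles x {FF, wT2, volume} CVs
    mean_volume: dict[str, float]           # muscle -> mean volume (mm^3)
    correlations: pd.DataFrame | None = None
    imbalance_curves: dict[str, dict[str, "reduce.ImbalanceResult"]] = \
        field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0


# ---------------------------------------------------------------------------
# study pieces

def muscle_volumes(cohort: Sequence[Subject],
                   slice_index: int | None = None) -> pd.DataFrame:
    """Per subject x muscle volume (mm^3) on one slice, sides averaged."""
    rows = []
    for subj in cohort:
        idx = subj.mid_slice_index if slice_index is None else slice_index
        sl = subj.slices[idx]
        mset = subj.masks[idx]
        for muscle in MUSCLES:
            vols = []
            for side in ("left", "right"):
                key = f"{muscle}_{side}"
                if key in mset.labels:
                    n = int(mset.labels[key].sum())
                    vols.append(n * sl.pixel_spacing ** 2
                                * sl.slice_thickness)
            rows.append({"subject_id": subj.subject_id, "muscle": muscle,
                         "volume_mm3": float(np.mean(vols))})
    return pd.DataFrame(rows)


def ground_truth_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    rows = []
    for subj in cohort:
        if subj.ground_truth is None:
            continue
        for muscle, gt in subj.ground_truth.items():
            rows.append({"subject_id": subj.subject_id, "muscle": muscle,
                         "FF_pp": gt["FF_pp"], "wT2_ms": gt["wT2_ms"]})
    return pd.DataFrame(rows)


def cv_summary(cohort: Sequence[Subject]) -> tuple[pd.DataFrame, dict]:
    """Muscle-wise coefficients of variation of ground-truth FF, wT2 and
    volume, plus the mean muscle volumes."""
    gt = ground_truth_frame(cohort)
    vol = muscle_volumes(cohort)
    rows, mean_vol = [], {}
    for muscle in MUSCLES:
        g = gt[gt.muscle == muscle]
        v = vol[vol.muscle == muscle]["volume_mm3"].to_numpy()
        rows.append({
            "muscle": muscle,
            "CV_FF": regress.coefficient_of_variation(g["FF_pp"].to_numpy()),
            "CV_wT2": regress.coefficient_of_variation(
                g["wT2_ms"].to_numpy()),
            "CV_volume": regress.coefficient_of_variation(v),
        })
        mean_vol[muscle] = float(v.mean())
    return pd.DataFrame(rows).set_index("muscle"), mean_vol


def run_workflow(wf_id: int, config: RunConfig,
                 feature_tables: dict[str, pd.DataFrame] | None = None,
                 wf3_tables: dict[str, dict[str, pd.DataFrame]] | None = None,
                 curves: dict | None = None,
                 ) -> dict[str, dict[str, dict[str, CvResult]]]:
    """One workflow's target -> muscle -> model CvResult grid.

    All cells share ``config.seed`` for the fold shuffle, so folds are
    identical across workflows and models.
    """
    out: dict[str, dict[str, dict[str, CvResult]]] = {}
    for target in config.targets:
        col = TARGET_COLUMN[target]
        out[target] = {}
        for muscle in MUSCLES:
            cell: dict[str, CvResult] = {}
            if wf_id == 3:
                tab = wf3_tables[muscle][target]
                x = tab.iloc[:, [0]].to_numpy(np.float64)   # FFG or MEG
                y = tab[col].to_numpy(np.float64)
                factories = {name: None for name in MODEL_NAMES}
            else:
                tab = feature_tables[muscle]
                x = tab[list(radiomics.FEATURE_CATALOG)].to_numpy(np.float64)
                y = tab[col].to_numpy(np.float64)
                if wf_id == 1:
                    if config.fit_scope == "global":
                        model = reduce.FoldPcaReducer(config.pca_components)
                        model.fit(x)
                        x = model.transform(x)
                        factories = {name: None for name in MODEL_NAMES}
                    else:
                        factories = {
                            name: (lambda: reduce.FoldPcaReducer(
                                config.pca_components))
                            for name in MODEL_NAMES}
                else:                                        # wf_id == 2
                    if curves is not None:
                        res = reduce.select_subset_by_imbalance(
                            tab, col, max_size=config.imbalance_max_size,
                            feature_names=list(radiomics.FEATURE_CATALOG))
                        curves.setdefault(target, {})[muscle] = res
                    if config.fit_scope == "global":
                        res = reduce.select_subset_by_imbalance(
                            tab, col, max_size=config.imbalance_max_size,
                            feature_names=list(radiomics.FEATURE_CATALOG))
                        cols = [list(radiomics.FEATURE_CATALOG).index(n)
                                for n in res.subset]
                        x = x[:, cols]
                        factories = {name: None for name in MODEL_NAMES}
                    else:
                        cache: dict = {}
                        factories = {
                            name: (lambda: reduce.FoldImbalanceReducer(
                                list(radiomics.FEATURE_CATALOG),
                                config.imbalance_max_size, cache))
                            for name in MODEL_NAMES}
            for name in MODEL_NAMES:
                spec = ModelSpec(name, seed=config.seed)
                cell[name] = regress.cross_validate(
                    x, y, spec, k=config.cv_folds, seed=config.seed,
                    reducer_factory=factories[name])
            out[target][muscle] = cell
    return out


def run_study(config: RunConfig,
              fshd_cohort: Sequence[Subject] | None = None,
              hc_cohort: Sequence[Subject] | None = None) -> StudyReport:
    """Load (or accept) cohorts, preprocess, run the requested workflows
    and assemble the full report."""
    config.validate()
    if fshd_cohort is None:
        if config.fshd_dir is None:
            raise ValueError("no FSHD cohort given")
        fshd_cohort = phantoms.read_cohort(config.fshd_dir)
    if hc_cohort is None and config.hc_dir is not None:
        hc_cohort = phantoms.read_cohort(config.hc_dir)
    if 3 in config.workflows and hc_cohort is None:
        raise ValueError("workflow 3 requires an HC cohort")
    if config.normalize and hc_cohort:
        mcfg = preprocess.HistogramMatchConfig(config.n_quantiles)
        hc_cohort = preprocess.normalize_cohort(hc_cohort, mcfg)
        ref_subj = sorted(hc_cohort, key=lambda s: s.subject_id)[0]
        ref = ref_subj.slices[ref_subj.mid_slice_index]
        fshd_cohort = preprocess.normalize_cohort(fshd_cohort, mcfg,
                                                  reference=ref)
    feature_tables = None
    if {1, 2} & set(config.workflows):
        feature_tables = radiomics.build_feature_tables(
            fshd_cohort, n_levels=config.n_levels)
    wf3_tables = None
    if 3 in config.workflows:
        limits = wf3mod.compute_reference_limits(
            hc_cohort, bin_width=config.wf3_bin_width,
            pooling=config.wf3_pooling)
        wf3_tables = wf3mod.build_wf3_tables(fshd_cohort, limits)
    curves: dict = {}
    results = {}
    for wf_id in sorted(config.workflows):
        logger.info("running workflow %d (config %s, seed %d)",
                    wf_id, config.hash(), config.seed)
        results[wf_id] = run_workflow(
            wf_id, config, feature_tables=feature_tables,
            wf3_tables=wf3_tables,
            curves=curves if wf_id == 2 else None)
    cv_table, mean_vol = cv_summary(fshd_cohort)
    report = StudyReport(results=results, cv_table=cv_table,
                         mean_volume=mean_vol, imbalance_curves=curves,
                         config_hash=config.hash(), seed=config.seed)
    report.correlations = correlation_screen(report)
    return report


def correlation_screen(report: StudyReport) -> pd.DataFrame | None:
    """KNN mean MAE per muscle against the CV series and mean volume.

    Rows follow the study's screen: Vol-FF, Vol-wT2, FF-FF, wT2-wT2 (CV
    series vs the KNN mean MAE of the named target), plus the mean-volume
    pairings.
    """
    wf_id = max(report.results) if report.results else None
    if wf_id is None:
        return None
    grid = report.results[wf_id]
    rows = []
    pairings = [("Vol-FF", "CV_volume", "FF"), ("Vol-wT2", "CV_volume", "wT2"),
                ("FF-FF", "CV_FF", "FF"), ("wT2-wT2", "CV_wT2", "wT2")]
    for label, cv_col, target in pairings:
        if target not in grid:
            continue
        maes = np.array([grid[target][m]["KNN"].mean_mae for m in MUSCLES])
        series = report.cv_table[cv_col].to_numpy()
        try:
            c = regress.correlate(series, maes)
            rows.append({"pairing": label, "pearson_r": c.pearson_r,
                         "pearson_p": c.pearson_p, "spearman_r": c.spearman_r,
                         "spearman_p": c.spearman_p})
        except ValueError as exc:           # e.g. constant phantom volumes
            logger.warning("correlation %s skipped: %s", label, exc)
            rows.append({"pairing": label, "pearson_r": np.nan,
                         "pearson_p": np.nan, "spearman_r": np.nan,
                         "spearman_p": np.nan})
    for target in grid:
        maes = np.array([grid[target][m]["KNN"].mean_mae for m in MUSCLES])
        vols = np.array([report.mean_volume[m] for m in MUSCLES])
        try:
            c = regress.correlate(vols, maes)
            rows.append({"pairing": f"meanVol-{target}",
                         "pearson_r": c.pearson_r, "pearson_p": c.pearson_p,
                         "spearman_r": c.spearman_r,
                         "spearman_p": c.spearman_p})
        except ValueError as exc:
            logger.warning("correlation meanVol-%s skipped: %s", target, exc)
            rows.append({"pairing": f"meanVol-{target}", "pearson_r": np.nan,
                         "pearson_p": np.nan, "spearman_r": np.nan,
                         "spearman_p": np.nan})
    return pd.DataFrame(rows).set_index("pairing")


# ---------------------------------------------------------------------------
# output files

def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh)


def summarize(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the per-workflow MAE tables, the CV table, the correlation
    screen and the imbalance curves; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# stirqmri config={report.config_hash} seed={report.seed}"
    written = []
    for wf_id, by_target in report.results.items():
        for target, by_muscle in by_target.items():
            rows = []
            for muscle in MUSCLES:
                row = {"muscle": muscle}
                for model in MODEL_NAMES:
                    r = by_muscle[muscle][model]
                    row[model] = f"{r.mean_mae:.2f} ({r.sd:.2f})"
                rows.append(row)
            path = outdir / f"wf{wf_id}_{target}_mae.csv"
            _write_csv(pd.DataFrame(rows).set_index("muscle"), path, header)
            written.append(path)
    path = outdir / "cv_table.csv"
    _write_csv(report.cv_table, path, header)
    written.append(path)
    if report.correlations is not None:
        path = outdir / "correlations.csv"
        _write_csv(report.correlations, path, header)
        written.append(path)
    for target, by_muscle in report.imbalance_curves.items():
        for muscle, res in by_muscle.items():
            path = outdir / f"imbalance_curve_{target}_{muscle}.csv"
            _write_csv(res.curve_frame().set_index("size"), path, header)
            written.append(path)
    report_json = {
        "config_hash": report.config_hash, "seed": report.seed,
        "results": {
            str(wf): {t: {m: {name: {"fold_maes": r.fold_maes,
                                     "mean_mae": r.mean_mae, "sd": r.sd}
                              for name, r in mm.items()}
                          for m, mm in tt.items()}
                      for t, tt in ww.items()}
            for wf, ww in report.results.items()},
        "mean_volume": report.mean_volume,
    }
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report_json, fh, indent=1, sort_keys=True)
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# CLI

def _cmd_simulate(args) -> int:
    out = Path(args.output)
    fshd = phantoms.generate_fshd_cohort(
        PhantomParams(n_subjects=args.n_fshd, seed=args.seed))
    phantoms.write_cohort(fshd, out / "fshd")
    hc = phantoms.generate_hc_cohort(
        PhantomParams(n_subjects=args.n_hc, seed=args.hc_seed))
    phantoms.write_cohort(hc, out / "hc")
    logger.info("wrote %d FSHD + %d HC subjects under %s",
                len(fshd), len(hc), out)
    return 0


def _cmd_extract(args) -> int:
    cohort = phantoms.read_cohort(Path(args.input) / "fshd")
    tables = radiomics.build_feature_tables(cohort)
    out = Path(args.output)
    out.mkdir(parents=True, exist_ok=True)
    for muscle, df in tables.items():
        df.to_csv(out / f"features_{muscle}.csv")
    return 0


def _cmd_limits(args) -> int:
    hc = phantoms.read_cohort(Path(args.input) / "hc")
    limits = wf3mod.compute_reference_limits(hc, bin_width=args.bin_width)
    limits.to_json(args.output)
    logger.info("LL=%.2f UL=%s", limits.LL,
                {k: round(v, 2) for k, v in limits.UL.items()})
    return 0


def _cmd_run(args) -> int:
    root = Path(args.input)
    config = RunConfig(
        fshd_dir=str(root / "fshd"),
        hc_dir=str(root / "hc") if (root / "hc").exists() else None,
        workflows=tuple(args.wf), seed=args.seed,
        output_dir=args.output, normalize=not args.no_normalize,
        fit_scope=args.fit_scope)
    config.validate()
    report = run_study(config)
    summarize(report, args.output)
    return 0


def _cmd_report(args) -> int:
    path = Path(args.input) / "report.json"
    if not path.exists():
        raise FileNotFoundError(f"missing report: {path}")
    with open(path) as fh:
        rep = json.load(fh)
    header = (f"# stirqmri config={rep['config_hash']} "
              f"seed={rep['seed']}")
    out = Path(args.output or args.input)
    for wf, by_target in rep["results"].items():
        for target, by_muscle in by_target.items():
            rows = []
            for muscle in MUSCLES:
                row = {"muscle": muscle}
                for model in MODEL_NAMES:
                    r = by_muscle[muscle][model]
                    row[model] = f"{r['mean_mae']:.2f} ({r['sd']:.2f})"
                rows.append(row)
            _write_csv(pd.DataFrame(rows).set_index("muscle"),
                       out / f"wf{wf}_{target}_mae.csv", header)
    return 0


def build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="stirqmri",
        description="Predict muscle fat fraction and water T2 from "
                    "STIR-like images via radiomics + ML workflows.")
    sub = p.add_subparsers(dest="command", required=True)

    sim = sub.add_parser("simulate", help="generate phantom cohorts")
    sim.add_argument("--n-fshd", type=int, default=25)
    sim.add_argument("--n-hc", type=int, default=6)
    sim.add_argument("--seed", type=int, default=1234)
    sim.add_argument("--hc-seed", type=int, default=7)
    sim.add_argument("-o", "--output", required=True)
    sim.set_defaults(func=_cmd_simulate)

    ext = sub.add_parser("extract", help="extract radiomic feature tables")
    ext.add_argument("-i", "--input", required=True)
    ext.add_argument("-o", "--output", required=True)
    ext.set_defaults(func=_cmd_extract)

    lim = sub.add_parser("limits", help="compute HC reference limits")
    lim.add_argument("-i", "--input", required=True)
    lim.add_argument("-o", "--output", required=True)
    lim.add_argument("--bin-width", type=float, default=1.0)
    lim.set_defaults(func=_cmd_limits)

    run = sub.add_parser("run", help="run workflows end to end")
    run.add_argument("--wf", type=int, nargs="+", choices=(1, 2, 3),
                     default=[3])
    run.add_argument("-i", "--input", required=True)
    run.add_argument("-o", "--output", required=True)
    run.add_argument("--seed", type=int, default=0)
    run.add_argument("--no-normalize", action="store_true")
    run.add_argument("--fit-scope", choices=("fold", "global"),
                     default="fold")
    run.set_defaults(func=_cmd_run)

    rep = sub.add_parser("report", help="re-summarize a saved report")
    rep.add_argument("-i", "--input", required=True)
    rep.add_argument("-o", "--output", default=None)
    rep.set_defaults(func=_cmd_report)
    return p


def main(argv: Sequence[str] | None = None) -> int:
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")
    parser = build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:               # argparse exits 2 on bad flags
        return int(exc.code or 0)
    try:
        return args.func(args)
    except Exception as exc:
        logger.error("%s", exc)
        return 1


if __name__ == "__main__":                  # pragma: no cover
    sys.exit(main())
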