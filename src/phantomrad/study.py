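"""End-to-end robustness study: simulate, extract, assess, summarize.

The study design: one texture phantom imaged under a reference protocol
and twelve single-factor variants; 93 features extracted per (protocol,
material); per-factor reproducibility (ICC, CCC over the 28 materials)
and variability (CV, QCD per material pair, aggregated over materials);
per-material variability across the 13 protocols; interpretation-bin
percentages over the 93 features.

Two surfaces are provided: plain functions mirroring the pipeline stages
(:func:`run_suite`, :func:`reproducibility_per_factor`, ...) and a
model/results pair (:class:`RobustnessStudy` -> :class:`RobustnessResults`)
for interactive use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquire import build_rois, simulate_acquisition
from .features import ExtractionSettings, FEATURE_NAMES, extract_feature_vector
from .phantom import PhantomLayout, build_default_layout, generate_ground_truth
from .protocols import (DEFAULT_REPOSITION, ProtocolSpec, RigidTransform,
                        SurrogateParams, default_protocol_suite)
from .stats import (PairedDesign, ReliabilityResult, VariabilityResult,
                    classify, coefficient_of_variation, icc_absolute_agreement,
                    lin_ccc, quartile_coefficient_of_dispersion)

__all__ = [
    "StudyConfig", "FeatureTable", "RobustnessSummary",
    "run_suite", "reproducibility_per_factor", "variability_per_factor",
    "variability_pairs", "variability_per_material", "summarize",
    "write_report", "RobustnessStudy", "RobustnessResults",
]


# --------------------------------------------------------------- config

@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run.

    The full-scale defaults mirror the physical study (400 mm FOV, 512
    matrix, 0.25 mm truth grid, 35 px ROIs over 25 layers).
    :meth:`compact` returns a geometry-preserving reduced configuration
    (identical pixel pitches and FOV ratios on a 100 mm phantom) for
    replicate-based analyses.
    """

    fov: float = 400.0
    matrix: int = 512
    insert_diameter: float = 32.0
    fine_spacing: float = 0.25
    slab_mm: float = 32.0
    roi_diameter_px: int = 35
    roi_n_layers: int = 25
    extraction: ExtractionSettings = field(default_factory=ExtractionSettings)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    reposition: RigidTransform = DEFAULT_REPOSITION
    protocols: tuple[str, ...] = ()   # empty = full 13-protocol suite
    variability_aggregation: str = "mean"   # mean | median over materials
    master_seed: int = 0

    @classmethod
    def compact(cls, master_seed: int = 0) -> "StudyConfig":
        """Quarter-scale configuration with identical voxel pitches."""
        return cls(fov=100.0, matrix=128, insert_diameter=8.0,
                   slab_mm=16.0, roi_diameter_px=9, roi_n_layers=7,
                   master_seed=master_seed)

    def build_layout(self) -> PhantomLayout:
        return build_default_layout(fov=self.fov,
                                    insert_diameter=self.insert_diameter,
                                    fine_spacing=self.fine_spacing,
                                    slab_mm=self.slab_mm)

    def build_suite(self) -> list[ProtocolSpec]:
        suite = default_protocol_suite(matrix=self.matrix, fov=self.fov)
        if self.protocols:
            wanted = set(self.protocols) | {"reference"}
            suite = [p for p in suite if p.id in wanted]
        return suite

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reposition"] = {"translation": list(self.reposition.translation),
                           "rotation_z": self.reposition.rotation_z}
        d["protocols"] = list(self.protocols)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "extraction" in d and isinstance(d["extraction"], dict):
            d["extraction"] = ExtractionSettings(**d["extraction"])
        if "surrogate" in d and isinstance(d["surrogate"], dict):
            sur = dict(d["surrogate"])
            for key in ("qir_noise_factor", "qir_extra_corr_px"):
                if key in sur:
                    sur[key] = {int(k): v for k, v in sur[key].items()}
            d["surrogate"] = SurrogateParams(**sur)
        if "reposition" in d and isinstance(d["reposition"], dict):
            rp = d["reposition"]
            d["reposition"] = RigidTransform(
                translation=tuple(rp.get("translation", (0, 0, 0))),
                rotation_z=float(rp.get("rotation_z", 0.0)))
        if "protocols" in d:
            d["protocols"] = tuple(d["protocols"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------- feature table

class FeatureTable:
    """Extracted features for every (protocol, material) cell.

    ``wide`` has one row per cell with columns ``protocol_id``,
    ``material_label`` and the 93 feature names in fixed order;
    ``degenerate`` is a parallel boolean frame over the feature columns.
    """

    def __init__(self, wide: pd.DataFrame, degenerate: pd.DataFrame,
                 provenance: dict | None = None):
        self.wide = wide.reset_index(drop=True)
        self.degenerate = degenerate.reset_index(drop=True)
        self.provenance = provenance or {}

    @property
    def protocol_ids(self) -> list[str]:
        return list(dict.fromkeys(self.wide["protocol_id"]))

    @property
    def material_labels(self) -> list[int]:
        return sorted(self.wide["material_label"].unique())

    def __len__(self) -> int:
        return len(self.wide)

    def values_for(self, protocol_id: str) -> pd.DataFrame:
        sub = self.wide[self.wide["protocol_id"] == protocol_id]
        if sub.empty:
            raise KeyError(f"protocol {protocol_id!r} not in the table")
        return sub.set_index("material_label")[list(FEATURE_NAMES)].sort_index()

    def to_long(self) -> pd.DataFrame:
        long = self.wide.melt(id_vars=["protocol_id", "material_label"],
                              value_vars=list(FEATURE_NAMES),
                              var_name="feature_name", value_name="value")
        deg = self.degenerate.copy()
        deg[["protocol_id", "material_label"]] = \
            self.wide[["protocol_id", "material_label"]]
        deg_long = deg.melt(id_vars=["protocol_id", "material_label"],
                            value_vars=list(FEATURE_NAMES),
                            var_name="feature_name",
                            value_name="degenerate_flag")
        long["degenerate_flag"] = deg_long["degenerate_flag"]
        long["family"] = long["feature_name"].str.split("_").str[0]
        return long[["protocol_id", "material_label", "feature_name",
                     "family", "value", "degenerate_flag"]]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.wide.to_csv(outdir / "feature_table.csv", index=False)
        self.to_long().to_csv(outdir / "feature_table_long.csv", index=False)
        (outdir / "feature_table_provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, wide_path, provenance: dict | None = None
                 ) -> "FeatureTable":
        wide = pd.read_csv(wide_path)
        deg = pd.DataFrame(False, index=wide.index,
                           columns=list(FEATURE_NAMES))
        return cls(wide, deg, provenance)


# ------------------------------------------------------------- pipeline

def run_suite(config: StudyConfig, seed: int | None = None) -> FeatureTable:
    """Run the full study: one ground truth, all protocols, all features.

    The ground truth is generated once from the master seed and shared by
    every protocol; each protocol gets an independent child seed for its
    noise realization.  Fully deterministic for a fixed seed.
    """
    master = config.master_seed if seed is None else seed
    layout = config.build_layout()
    suite = config.build_suite()
    reference = suite[0]
    ss = np.random.SeedSequence(master)
    truth_seed, *proto_seeds = ss.spawn(1 + len(suite))

    try:
        truth, labels = generate_ground_truth(layout, truth_seed)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"[ground-truth] {exc}") from exc

    rows, deg_rows = [], []
    for protocol, pseed in zip(suite, proto_seeds):
        transform = (config.reposition if protocol.id == "reposition"
                     else RigidTransform())
        try:
            image = simulate_acquisition(truth, protocol, transform,
                                         seed=pseed,
                                         params=config.surrogate,
                                         labels=labels, layout=layout)
            rois = build_rois(protocol, layout, transform,
                              diameter_px=config.roi_diameter_px,
                              n_layers=config.roi_n_layers,
                              snap_grid=replace(reference, fov=layout.fov))
        except Exception as exc:
            raise RuntimeError(f"[simulate:{protocol.id}] {exc}") from exc
        for label in rois.material_labels:
            try:
                fv = extract_feature_vector(image, rois.mask(label),
                                            config.extraction)
            except Exception as exc:
                raise RuntimeError(
                    f"[extract:{protocol.id}:{label}] {exc}") from exc
            row = {"protocol_id": protocol.id, "material_label": label}
            row.update(fv.as_dict())
            rows.append(row)
            deg_rows.append({name: fv.is_degenerate(name)
                             for name in FEATURE_NAMES})

    wide = pd.DataFrame(rows, columns=["protocol_id", "material_label",
                                       *FEATURE_NAMES])
    deg = pd.DataFrame(deg_rows, columns=list(FEATURE_NAMES))
    provenance = {"master_seed": int(master),
                  "settings_hash": config.extraction.settings_hash(),
                  "n_protocols": len(suite),
                  "n_materials": layout.n_materials}
    return FeatureTable(wide, deg, provenance)


FACTOR_LABELS = {
    "reposition": "Reposition",
    "high_pitch": "High-pitch scan",
    "kvp140": "Tube voltage",
    "slice04": "Slice thickness",
    "dose05": "Dose 0.5 mGy",
    "dose10": "Dose 1.0 mGy",
    "dose30": "Dose 3.0 mGy",
    "dose50": "Dose 5.0 mGy",
    "qir0": "QIR level 0",
    "qir2": "QIR level 2",
    "qr44": "Kernel Qr44",
    "qr48": "Kernel Qr48",
}


def reproducibility_per_factor(table: FeatureTable, reference_id: str,
                               comparison_id: str) -> list[ReliabilityResult]:
    """ICC(A,1) and CCC per feature over the materials x {ref, comp} design."""
    ref = table.values_for(reference_id)
    comp = table.values_for(comparison_id)
    shared = ref.index.intersection(comp.index)
    results = []
    for name in FEATURE_NAMES:
        x = ref.loc[shared, name].to_numpy()
        y = comp.loc[shared, name].to_numpy()
        design = PairedDesign(np.column_stack([x, y]),
                              subjects=tuple(shared),
                              protocols=(reference_id, comparison_id))
        rr = icc_absolute_agreement(design, feature=name)
        rr.ccc = lin_ccc(x, y)
        results.append(rr)
    return results


def variability_pairs(table: FeatureTable, reference_id: str,
                      comparison_id: str) -> pd.DataFrame:
    """Per (feature, material) CV and QCD over the {ref, comp} value pair."""
    ref = table.values_for(reference_id)
    comp = table.values_for(comparison_id)
    shared = ref.index.intersection(comp.index)
    records = []
    for name in FEATURE_NAMES:
        for label in shared:
            pair = np.array([ref.loc[label, name], comp.loc[label, name]])
            cv = coefficient_of_variation(pair)
            qcd = quartile_coefficient_of_dispersion(pair)
            records.append({"feature": name, "material_label": int(label),
                            "cv": cv.cv, "qcd": qcd.qcd,
                            "undefined": bool(cv.undefined or qcd.undefined)})
    return pd.DataFrame.from_records(records)


def variability_per_factor(table: FeatureTable, reference_id: str,
                           comparison_id: str,
                           aggregation: str = "mean"
                           ) -> list[VariabilityResult]:
    """Per-feature CV/QCD for one factor, aggregated over materials.

    CV and QCD are computed per material on the {reference, comparison}
    value pair, then averaged (or median-pooled) over materials; undefined
    pairs (zero denominator) are excluded with their count reported via
    the result's ``n``.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    pairs = variability_pairs(table, reference_id, comparison_id)
    agg = np.nanmean if aggregation == "mean" else np.nanmedian
    out = []
    for name, grp in pairs.groupby("feature", sort=False):
        cvs = grp["cv"].to_numpy()
        qcds = grp["qcd"].to_numpy()
        cv_ok = np.isfinite(cvs)
        qcd_ok = np.isfinite(qcds)
        res = VariabilityResult(
            feature=name,
            cv=float(agg(cvs)) if cv_ok.any() else np.nan,
            qcd=float(agg(qcds)) if qcd_ok.any() else np.nan,
            n=int(min(cv_ok.sum(), qcd_ok.sum())),
            undefined=not (cv_ok.any() and qcd_ok.any()))
        out.append(res)
    return out


def variability_per_material(table: FeatureTable,
                             material_label: int) -> list[VariabilityResult]:
    """Per-feature CV/QCD across all protocols for one material."""
    sub = table.wide[table.wide["material_label"] == material_label]
    if len(sub) < len(table.protocol_ids):
        missing = set(table.protocol_ids) - set(sub["protocol_id"])
        raise ValueError(f"material {material_label} missing from protocols "
                         f"{sorted(missing)}")
    out = []
    for name in FEATURE_NAMES:
        vals = sub[name].to_numpy()
        cv = coefficient_of_variation(vals)
        qcd = quartile_coefficient_of_dispersion(vals)
        out.append(VariabilityResult(
            feature=name, cv=cv.cv, qcd=qcd.qcd, q1=qcd.q1, q3=qcd.q3,
            n=vals.size, undefined=bool(cv.undefined or qcd.undefined)))
    return out


# ------------------------------------------------------------- summaries

def _describe(values: np.ndarray) -> dict:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan,
                "q1": np.nan, "q3": np.nan, "n": 0}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "n": int(v.size)}


def _bin_percent(values: np.ndarray, metric: str, bins: tuple) -> dict:
    n = len(values)
    labels = [classify(v, metric) for v in values]
    out = {}
    for b in bins + ("undefined",):
        out[b] = round(100.0 * labels.count(b) / n, 1)
    return out


@dataclass
class RobustnessSummary:
    """Aggregated study results in the layout of the summary tables.

    Percentages are over the 93 features (one decimal), with an explicit
    ``undefined`` bin rather than silent exclusion.
    """

    reliability_by_factor: pd.DataFrame
    reliability_bins: pd.DataFrame
    variability_by_factor: pd.DataFrame
    variability_bins_by_factor: pd.DataFrame
    variability_by_material: pd.DataFrame
    variability_bins_by_material: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def df_dict(df):
            return json.loads(df.to_json(orient="split"))
        return {
            "reliability_by_factor": df_dict(self.reliability_by_factor),
            "reliability_bins": df_dict(self.reliability_bins),
            "variability_by_factor": df_dict(self.variability_by_factor),
            "variability_bins_by_factor":
                df_dict(self.variability_bins_by_factor),
            "variability_by_material": df_dict(self.variability_by_material),
            "variability_bins_by_material":
                df_dict(self.variability_bins_by_material),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RobustnessSummary":
        def dict_df(obj):
            return pd.DataFrame(obj["data"], index=obj["index"],
                                columns=obj["columns"])
        return cls(
            reliability_by_factor=dict_df(d["reliability_by_factor"]),
            reliability_bins=dict_df(d["reliability_bins"]),
            variability_by_factor=dict_df(d["variability_by_factor"]),
            variability_bins_by_factor=dict_df(d["variability_bins_by_factor"]),
            variability_by_material=dict_df(d["variability_by_material"]),
            variability_bins_by_material=
                dict_df(d["variability_bins_by_material"]),
            provenance=d.get("provenance", {}),
        )


RELIABILITY_BIN_NAMES = ("poor", "moderate", "good", "excellent")
VARIABILITY_BIN_NAMES = ("acceptable", "moderate", "inadequate")


def summarize(table: FeatureTable,
              reference_id: str = "reference",
              aggregation: str = "mean") -> RobustnessSummary:
    """Compute the per-factor and per-material summary blocks."""
    factors = [p for p in table.protocol_ids if p != reference_id]

    rel_rows, rel_bin_rows = {}, {}
    var_rows, var_bin_rows = {}, {}
    for fid in factors:
        rel = reproducibility_per_factor(table, reference_id, fid)
        icc = np.array([r.icc for r in rel])
        ccc = np.array([r.ccc for r in rel])
        row = {}
        for key, vals in (("icc", icc), ("ccc", ccc)):
            desc = _describe(vals)
            row.update({f"{key}_{k}": v for k, v in desc.items()})
        rel_rows[fid] = row
        rel_bin_rows[fid] = {
            **{f"icc_{b}": v for b, v in _bin_percent(
                icc, "reliability", RELIABILITY_BIN_NAMES).items()},
            **{f"ccc_{b}": v for b, v in _bin_percent(
                ccc, "reliability", RELIABILITY_BIN_NAMES).items()},
        }

        pairs = variability_pairs(table, reference_id, fid)
        per_feature = variability_per_factor(table, reference_id, fid,
                                             aggregation=aggregation)
        cv_pool = pairs["cv"].to_numpy()
        qcd_pool = pairs["qcd"].to_numpy()
        row = {}
        for key, vals in (("cv", cv_pool), ("qcd", qcd_pool)):
            desc = _describe(vals)
            row.update({f"{key}_{k}": v for k, v in desc.items()})
        var_rows[fid] = row
        cv_feat = np.array([r.cv for r in per_feature])
        qcd_feat = np.array([r.qcd for r in per_feature])
        var_bin_rows[fid] = {
            **{f"cv_{b}": v for b, v in _bin_percent(
                cv_feat, "variability", VARIABILITY_BIN_NAMES).items()},
            **{f"qcd_{b}": v for b, v in _bin_percent(
                qcd_feat, "variability", VARIABILITY_BIN_NAMES).items()},
        }

    mat_rows, mat_bin_rows = {}, {}
    for label in table.material_labels:
        res = variability_per_material(table, label)
        cv = np.array([r.cv for r in res])
        qcd = np.array([r.qcd for r in res])
        row = {}
        for key, vals in (("cv", cv), ("qcd", qcd)):
            desc = _describe(vals)
            row.update({f"{key}_{k}": v for k, v in desc.items()})
        mat_rows[label] = row
        mat_bin_rows[label] = {
            **{f"cv_{b}": v for b, v in _bin_percent(
                cv, "variability", VARIABILITY_BIN_NAMES).items()},
            **{f"qcd_{b}": v for b, v in _bin_percent(
                qcd, "variability", VARIABILITY_BIN_NAMES).items()},
        }

    return RobustnessSummary(
        reliability_by_factor=pd.DataFrame.from_dict(rel_rows, orient="index"),
        reliability_bins=pd.DataFrame.from_dict(rel_bin_rows, orient="index"),
        variability_by_factor=pd.DataFrame.from_dict(var_rows, orient="index"),
        variability_bins_by_factor=pd.DataFrame.from_dict(var_bin_rows,
                                                          orient="index"),
        variability_by_material=pd.DataFrame.from_dict(mat_rows,
                                                       orient="index"),
        variability_bins_by_material=pd.DataFrame.from_dict(mat_bin_rows,
                                                            orient="index"),
        provenance=dict(table.provenance),
    )


def write_report(summary: RobustnessSummary, table: FeatureTable | None,
                 outdir, figures: bool = False) -> list[Path]:
    """Write summary.json, the per-table CSV analogs and optional figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    path = outdir / "summary.json"
    path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    written.append(path)

    for name, df in (
        ("table2_reliability.csv", summary.reliability_by_factor),
        ("table3_variability_factor.csv", summary.variability_by_factor),
        ("table4_variability_material.csv", summary.variability_by_material),
        ("bins_reliability.csv", summary.reliability_bins),
        ("bins_variability_factor.csv", summary.variability_bins_by_factor),
        ("bins_variability_material.csv",
         summary.variability_bins_by_material),
    ):
        p = outdir / name
        df.to_csv(p)
        written.append(p)

    if table is not None:
        table.save(outdir)
        written.append(outdir / "feature_table.csv")

    if figures:
        written.extend(_write_figures(summary, outdir))
    return written


def _write_figures(summary: RobustnessSummary, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    specs = [
        ("fig3_reliability_bins.png", summary.reliability_bins,
         ["icc_" + b for b in RELIABILITY_BIN_NAMES],
         "% of features per ICC bin"),
        ("fig4_variability_bins.png", summary.variability_bins_by_factor,
         ["cv_" + b for b in VARIABILITY_BIN_NAMES],
         "% of features per CV bin"),
        ("fig5_material_bins.png", summary.variability_bins_by_material,
         ["cv_" + b for b in VARIABILITY_BIN_NAMES],
         "% of features per CV bin (per material)"),
    ]
    for fname, df, cols, title in specs:
        cols = [c for c in cols if c in df.columns]
        fig, ax = plt.subplots(figsize=(10, 4))
        df[cols].plot(kind="bar", stacked=True, ax=ax, width=0.8)
        ax.set_ylabel("% of 93 features")
        ax.set_title(title)
        fig.tight_layout()
        p = outdir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


# ------------------------------------------------- model/results objects

class RobustnessStudy:
    """Model object for the robustness study.

    Construct from a :class:`StudyConfig` (simulation + extraction run on
    demand) or from an existing :class:`FeatureTable` via
    :meth:`from_feature_table`; :meth:`fit` computes all robustness
    statistics and returns a :class:`RobustnessResults`.
    """

    def __init__(self, config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        self._table: FeatureTable | None = None

    @classmethod
    def from_feature_table(cls, table: FeatureTable,
                           config: StudyConfig | None = None
                           ) -> "RobustnessStudy":
        obj = cls(config)
        obj._table = table
        return obj

    def run(self, seed: int | None = None) -> FeatureTable:
        """Simulate + extract (cached); ``seed`` overrides the config seed."""
        if self._table is None or seed is not None:
            self._table = run_suite(self.config, seed=seed)
        return self._table

    def fit(self, seed: int | None = None) -> "RobustnessResults":
        table = self.run(seed=seed)
        summary = summarize(table,
                            aggregation=self.config.variability_aggregation)
        return RobustnessResults(self, table, summary)


class RobustnessResults:
    """Fitted robustness statistics with summary tables and plots."""

    def __init__(self, model: RobustnessStudy, table: FeatureTable,
                 tables: RobustnessSummary):
        self.model = model
        self.feature_table = table
        self.tables = tables

    @property
    def reliability_by_factor(self) -> pd.DataFrame:
        return self.tables.reliability_by_factor

    @property
    def variability_by_factor(self) -> pd.DataFrame:
        return self.tables.variability_by_factor

    @property
    def variability_by_material(self) -> pd.DataFrame:
        return self.tables.variability_by_material

    def median_icc(self) -> pd.Series:
        return self.tables.reliability_by_factor["icc_median"]

    def percent_excellent(self, metric: str = "icc") -> pd.Series:
        return self.tables.reliability_bins[f"{metric}_excellent"]

    def save(self, outdir, figures: bool = False) -> list[Path]:
        return write_report(self.tables, self.feature_table, outdir,
                            figures=figures)

    def summary(self) -> str:
        """Human-readable study summary."""
        rel = self.tables.reliability_by_factor
        bins = self.tables.reliability_bins
        lines = ["Radiomics robustness study",
                 "=" * 60,
                 f"protocols: {len(self.feature_table.protocol_ids)}  "
                 f"materials: {len(self.feature_table.material_labels)}  "
                 f"features: {len(FEATURE_NAMES)}",
                 "",
                 "Reproducibility vs reference (per factor)",
                 f"{'factor':<14}{'ICC med':>9}{'CCC med':>9}"
                 f"{'%ICC>=0.90':>12}"]
        for fid in rel.index:
            lines.append(
                f"{fid:<14}{rel.loc[fid, 'icc_median']:>9.3f}"
                f"{rel.loc[fid, 'ccc_median']:>9.3f}"
                f"{bins.loc[fid, 'icc_excellent']:>12.1f}")
        var = self.tables.variability_by_factor
        lines += ["", "Variability vs reference (pooled CV/QCD, %)",
                  f"{'factor':<14}{'CV med':>9}{'QCD med':>9}"]
        for fid in var.index:
            lines.append(f"{fid:<14}{var.loc[fid, 'cv_median']:>9.1f}"
                         f"{var.loc[fid, 'qcd_median']:>9.1f}")
        return "\n".join(lines)
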