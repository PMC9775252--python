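"""End-to-end orchestration: simulate/load -> preprocess -> connectivity ->
network metrics -> group comparisons -> classification, with deterministic
seeding and a checksummed run manifest.

Every stage is also exposed as a standalone function operating on on-disk
artifacts so the CLI subcommands compose to exactly the same outputs as a
single :func:`run_pipeline` call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    DEFAULT_FEATURES,
    ClassifierReport,
    SubjectFeatures,
    crossval_classify,
    extract_features,
    features_frame,
    group_compare,
    metrics_table,
)
from .connectivity import (
    ANALYZED_CONDITIONS,
    segment_connectivity,
    write_long_tsv,
    write_matrix_csv,
)
from .errors import ConfigurationError
from .graphnet import binarize, write_edge_list
from .preprocess import (
    BAND_BY_NAME,
    CHANNELS_19,
    ConditionSegment,
    bandpass_filter,
    common_average_reference,
    select_channels,
)
from .synthdata import (
    CouplingSpec,
    LabeledRecording,
    SimulationConfig,
    iter_cohort,
    read_cohort,
)

log = logging.getLogger("plvnet")


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    synth: SimulationConfig | None = None
    input_dir: str | None = None
    band_names: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    prefilter: tuple[float, float] = (0.1, 30.0)
    threshold_fraction: float = 0.8
    edge_exclusion: float = 1.0
    analyzed_conditions: tuple[str, ...] = ANALYZED_CONDITIONS
    n_permutations: int = 9999
    feature_spec: tuple[str, ...] = DEFAULT_FEATURES
    classify_condition: str = "pre"
    cv_folds: int = 10
    seed: int = 0
    write_matrices: bool = True
    write_graphs: bool = False

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one input source required: synth or input_dir"
            )
        for name in self.band_names:
            if name not in BAND_BY_NAME:
                raise ConfigurationError(f"unknown band {name!r}")

    @property
    def bands(self):
        return tuple(BAND_BY_NAME[n] for n in self.band_names)

    # -- lossless (de)serialization -----------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            coupling = [
                {
                    "group": g, "condition": c, "band": b,
                    "strength": s.strength,
                    "phase_jitter_sd": s.phase_jitter_sd,
                    "coupled_pairs": (
                        None if s.coupled_pairs is None
                        else sorted(sorted(p) for p in s.coupled_pairs)
                    ),
                }
                for (g, c, b), s in sorted(self.synth.band_coupling.items())
            ]
            d["synth"] = {
                "n_per_group": self.synth.n_per_group,
                "sampling_rate": self.synth.sampling_rate,
                "segment_layout": [list(x) for x in self.synth.segment_layout],
                "channel_labels": list(self.synth.channel_labels),
                "band_coupling": coupling,
                "noise_sd": self.synth.noise_sd,
                "seed": self.synth.seed,
                "subject_strength_sd": self.synth.subject_strength_sd,
            }
        for key in ("band_names", "prefilter", "analyzed_conditions",
                    "feature_spec"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synth", None)
        if synth is not None:
            coupling = {}
            for entry in synth["band_coupling"]:
                pairs = entry["coupled_pairs"]
                coupling[(entry["group"], entry["condition"], entry["band"])] = (
                    CouplingSpec(
                        BAND_BY_NAME[entry["band"]], entry["strength"],
                        None if pairs is None
                        else frozenset(frozenset(p) for p in pairs),
                        entry["phase_jitter_sd"],
                    )
                )
            synth = SimulationConfig(
                n_per_group=synth["n_per_group"],
                sampling_rate=synth["sampling_rate"],
                segment_layout=tuple(tuple(x) for x in synth["segment_layout"]),
                channel_labels=tuple(synth["channel_labels"]),
                band_coupling=coupling,
                noise_sd=synth["noise_sd"],
                seed=synth["seed"],
                subject_strength_sd=synth["subject_strength_sd"],
            )
        for key in ("band_names", "prefilter", "analyzed_conditions",
                    "feature_spec"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(synth=synth, **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls.from_dict(data)


def default_config(n_per_group: int = 8, seed: int = 0) -> PipelineConfig:
    """The standard synthetic-cohort run (paper-like session layout)."""
    return PipelineConfig(synth=SimulationConfig(n_per_group=n_per_group,
                                                 seed=seed), seed=seed)


def _child_seed(master: int, tag: str) -> int:
    """Stable per-stage integer seed derived from the master seed."""
    ss = np.random.SeedSequence([master, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# Stages

def preprocess_labeled(labeled: LabeledRecording,
                       prefilter=(0.1, 30.0),
                       keep=CHANNELS_19):
    """Channel selection, common average reference, broadband bandpass.

    Returns ``(labeled, segment)`` with the whole (per-condition) recording
    wrapped as one ConditionSegment.
    """
    rec = labeled.recording
    if set(keep) <= set(rec.channel_labels):
        rec = select_channels(rec, keep)
    rec = common_average_reference(rec)
    rec = bandpass_filter(rec, *prefilter)
    segment = ConditionSegment(rec, labeled.condition, 0.0, rec.duration)
    return dataclasses.replace(labeled, recording=rec), segment


def compare_table(features, band_names, n_permutations: int,
                  master_seed: int) -> pd.DataFrame:
    """All group/condition contrasts for mean CC and CPL per band."""
    rows = []
    by = {}
    for f in features:
        by.setdefault((f.group, f.condition), []).append(f)
    for band in band_names:
        for metric in ("mean_cc", "cpl"):
            def vals(group, condition):
                cell = sorted(by.get((group, condition), []),
                              key=lambda f: f.subject_id)
                table = {"mean_cc": lambda f: f.mean_cc[band],
                         "cpl": lambda f: f.cpl[band]}[metric]
                return [table(f) for f in cell]

            contrasts = [
                ("MDD-pre_vs_HC-pre", vals("MDD", "pre"), vals("HC", "pre"), False),
                ("MDD-pre_vs_MDD-post", vals("MDD", "pre"), vals("MDD", "post"), True),
            ]
            for name, a, b, paired in contrasts:
                if not a or not b:
                    continue
                seed = _child_seed(master_seed, f"compare/{name}/{band}/{metric}")
                res = group_compare(a, b, paired=paired,
                                    n_permutations=n_permutations, seed=seed)
                rows.append({
                    "contrast": name, "band": band, "metric": metric,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "n_permutations": res.n_permutations, "seed": seed,
                    "paired": paired, "exhaustive": res.exhaustive,
                })
    return pd.DataFrame(rows)


def classify_features(features, feature_spec=DEFAULT_FEATURES,
                      condition: str = "pre", k: int = 10,
                      seed: int = 0) -> ClassifierReport:
    X, y, names, _ = extract_features(features, feature_spec, condition,
                                      standardize=False)
    return crossval_classify(X, y, k=k, seed=seed, feature_names=names)


# ---------------------------------------------------------------------------
# Tabular artifact I/O

def write_metrics_tsv(path, features) -> None:
    df = features_frame(features)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metrics_tsv(path) -> list[SubjectFeatures]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sid, cond), cell in df.groupby(["subject", "condition"], sort=True):
        group = cell["group"].iloc[0]
        mean_cc, cpl, degrees = {}, {}, {}
        for band, sub in cell.groupby("band"):
            pivot = dict(zip(sub["metric"], sub["value"]))
            mean_cc[band] = pivot["mean_cc"]
            cpl[band] = pivot["cpl"]
            deg = sub[sub["metric"].str.startswith("degree_")].copy()
            deg["idx"] = deg["metric"].str.removeprefix("degree_").astype(int)
            degrees[band] = deg.sort_values("idx")["value"].to_numpy()
        out.append(SubjectFeatures(sid, group, cond, mean_cc, cpl, degrees))
    return out


def write_classifier_report(path, report: ClassifierReport) -> None:
    with open(path, "w") as fh:
        json.dump({
            "classifiers": report.results,
            "folds": report.folds,
            "seed": report.seed,
            "feature_names": list(report.feature_names),
            "n": report.n,
        }, fh, indent=1, sort_keys=True)


def write_table2_tsv(path, report: ClassifierReport) -> None:
    """Classifier summary shaped like the headline results table."""
    with open(path, "w") as fh:
        fh.write("classifier\taccuracy\tprecision\trecall\n")
        for name in ("KNN", "SVM", "DT", "RF"):
            if name not in report.results:
                continue
            r = report.results[name]
            fh.write(f"{name}\t{r['accuracy']:.6g}\t{r['precision']:.6g}\t"
                     f"{r['recall']:.6g}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Full run

def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, write the result bundle, return the manifest."""
    os.makedirs(outdir, exist_ok=True)
    probe = os.path.join(outdir, ".write_probe")
    try:
        with open(probe, "w") as fh:
            fh.write("ok")
    finally:
        if os.path.exists(probe):
            os.remove(probe)

    if config.synth is not None:
        cohort = iter_cohort(config.synth, conditions=config.analyzed_conditions)
    else:
        cohort = (
            rec for rec in read_cohort(config.input_dir)
            if rec.condition in config.analyzed_conditions
        )

    matrices = []
    matrices_dir = os.path.join(outdir, "matrices")
    if config.write_matrices:
        os.makedirs(matrices_dir, exist_ok=True)
    for labeled in cohort:
        log.info("subject %s condition %s", labeled.subject_id, labeled.condition)
        _, segment = preprocess_labeled(labeled, config.prefilter)
        for m in segment_connectivity(segment, config.bands,
                                      config.edge_exclusion,
                                      subject_id=labeled.subject_id,
                                      group=labeled.group):
            matrices.append(m)
            if config.write_matrices:
                fname = f"{m.subject_id}_{m.condition}_{m.band}.csv"
                write_matrix_csv(os.path.join(matrices_dir, fname), m)

    artifacts = {}
    if config.write_matrices:
        long_path = os.path.join(outdir, "connectivity_long.tsv")
        write_long_tsv(long_path, matrices)
        artifacts["connectivity_long.tsv"] = long_path

    if config.write_graphs:
        graphs_dir = os.path.join(outdir, "graphs")
        os.makedirs(graphs_dir, exist_ok=True)
        for m in matrices:
            g = binarize(m, config.threshold_fraction)
            fname = f"{m.subject_id}_{m.condition}_{m.band}_edges.tsv"
            write_edge_list(os.path.join(graphs_dir, fname), g)

    features = metrics_table(matrices, config.threshold_fraction)
    metrics_path = os.path.join(outdir, "metrics.tsv")
    write_metrics_tsv(metrics_path, features)
    artifacts["metrics.tsv"] = metrics_path

    comparisons = compare_table(features, config.band_names,
                                config.n_permutations, config.seed)
    comparisons_path = os.path.join(outdir, "comparisons.tsv")
    comparisons.to_csv(comparisons_path, sep="\t", index=False,
                       float_format="%.12g")
    artifacts["comparisons.tsv"] = comparisons_path

    report = classify_features(features, config.feature_spec,
                               config.classify_condition, config.cv_folds,
                               seed=_child_seed(config.seed, "classify"))
    report_path = os.path.join(outdir, "classifier_report.json")
    write_classifier_report(report_path, report)
    artifacts["classifier_report.json"] = report_path
    table2_path = os.path.join(outdir, "classifier_table.tsv")
    write_table2_tsv(table2_path, report)
    artifacts["classifier_table.tsv"] = table2_path

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "n_matrices": len(matrices),
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
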