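"""Experiment configuration, feature-pair expansion, and summary rendering.

CSV tables are the contract surface; bar figures (mean across subjects with
subject-wise min-max whiskers) are conveniences for eyeballing sweeps.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .degrade import DegradationSpec
from .evaluate import ClassifierSpec
from .features import FEATURE_NAMES, FeatureSpec
from .preprocess import PreprocessConfig
from .synth import GeneratorConfig

__all__ = ["ExperimentConfig", "expand_feature_pairs", "render_summary", "protocol_pivot"]


def expand_feature_pairs(
    base_features: list[str] | tuple[str, ...],
    pairs_with: str | None = None,
    **spec_kwargs,
) -> list[FeatureSpec]:
    """All singles plus all unordered pairs of ``base_features``, deduplicated,
    in deterministic (input) order.  With ``pairs_with`` set, return only the
    pairs that include that feature (e.g. every time-domain feature + MNF)."""
    base = list(dict.fromkeys(base_features))
    if not base:
        raise ValueError("need at least one base feature")
    for name in base + ([pairs_with] if pairs_with else []):
        if name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {name!r}")
    if pairs_with is not None:
        return [
            FeatureSpec(names=(f, pairs_with), **spec_kwargs)
            for f in base
            if f != pairs_with
        ]
    singles = [FeatureSpec(names=(f,), **spec_kwargs) for f in base]
    pairs = [
        FeatureSpec(names=(a, b), **spec_kwargs)
        for a, b in itertools.combinations(base, 2)
    ]
    return singles + pairs


@dataclass
class ExperimentConfig:
    """Declarative experiment: generator + preprocessing + condition grids."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    feature_specs: list[FeatureSpec] = field(
        default_factory=lambda: expand_feature_pairs(["RMS", "VAR", "ZC", "WL"])
    )
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec("rf")]
    )
    degradations: list[DegradationSpec] = field(default_factory=list)
    protocol: str = "pooled"
    n_repeats: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "generator" in raw:
            gen = dict(raw["generator"])
            if "gesture_labels" in gen:
                gen["gesture_labels"] = tuple(gen["gesture_labels"])
            if "band" in gen:
                gen["band"] = tuple(gen["band"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if "preprocess" in raw:
            pre = dict(raw["preprocess"])
            if "band" in pre:
                pre["band"] = tuple(pre["band"])
            kwargs["preprocess"] = PreprocessConfig(**pre)
        if "features" in raw:
            feats = raw["features"]
            if isinstance(feats, dict):  # {base: [...], pairs_with: ...}
                kwargs["feature_specs"] = expand_feature_pairs(
                    feats["base"], feats.get("pairs_with")
                )
            else:  # explicit list of name lists
                kwargs["feature_specs"] = [
                    FeatureSpec(names=tuple(names)) for names in feats
                ]
        if "classifiers" in raw:
            kwargs["classifiers"] = [
                ClassifierSpec(kind=c) if isinstance(c, str)
                else ClassifierSpec(kind=c["kind"], grid=c.get("grid"))
                for c in raw["classifiers"]
            ]
        if "degrade" in raw:
            degs = raw["degrade"]
            degs = degs if isinstance(degs, list) else [degs]
            kwargs["degradations"] = [DegradationSpec.from_dict(d) for d in degs]
        for key in ("protocol", "n_repeats", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        gen = dataclasses.asdict(self.generator)
        gen["gesture_labels"] = list(gen["gesture_labels"])
        gen["band"] = list(gen["band"])
        pre = dataclasses.asdict(self.preprocess)
        pre["band"] = list(pre["band"])
        doc = {
            "generator": gen,
            "preprocess": pre,
            "features": [list(fs.names) for fs in self.feature_specs],
            "classifiers": [
                {"kind": c.kind, **({"grid": c.grid} if c.grid else {})}
                for c in self.classifiers
            ],
            "degrade": [d.to_dict() for d in self.degradations],
            "protocol": self.protocol,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def protocol_pivot(summary: pd.DataFrame) -> pd.DataFrame:
    """One row per feature set, one column per protocol (mean accuracy) —
    the layout of an intra- vs inter-session comparison table."""
    if "protocol" not in summary.columns:
        raise ValueError("summary has no protocol column")
    return (
        summary.pivot_table(
            index="features", columns="protocol", values="mean_accuracy", sort=True
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )


def render_summary(
    summary: pd.DataFrame,
    out_dir: str | Path,
    style: str = "bars-minmax",
    stem: str = "summary",
) -> list[Path]:
    """Write the summary as deterministic artifacts.

    ``bars-minmax``: CSV plus a bar figure (bar = mean of per-subject means,
    whiskers = subject-wise min-max).  ``table``: CSV only; when a protocol
    column is present a feature x protocol pivot CSV is written as well.
    """
    if summary.empty:
        raise ValueError("empty summary")
    if style not in ("bars-minmax", "table"):
        raise ValueError(f"unknown style {style!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out_dir / f"{stem}.csv"
    summary.to_csv(csv_path, index=False)
    written.append(csv_path)

    if style == "table":
        if "protocol" in summary.columns and summary["protocol"].nunique() > 1:
            pivot_path = out_dir / f"{stem}_by_protocol.csv"
            protocol_pivot(summary).to_csv(pivot_path, index=False)
            written.append(pivot_path)
        return written

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [
        " | ".join(
            str(row[c])
            for c in ("features", "classifier", "degradation", "protocol")
            if c in summary.columns
        )
        for _, row in summary.iterrows()
    ]
    means = summary["mean_accuracy"].to_numpy()
    yerr = [
        means - summary["min_accuracy"].to_numpy(),
        summary["max_accuracy"].to_numpy() - means,
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(labels)), 4))
    ax.bar(range(len(labels)), means, yerr=yerr, capsize=4, color="#4878a8")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig_path = out_dir / f"{stem}.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    written.append(fig_path)
    return written
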