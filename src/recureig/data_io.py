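"""Dataset readers, result writers, and a synthetic cohort generator.

Two public data layouts are supported:

* label-prefixed delimited series tables (one record per line: a class
  label followed by the series values), the convention used by the
  time-series-classification archives that distribute the eigenworm
  amplitude traces;
* whitespace-delimited multi-column per-subject gait records, from which
  the left/right swing-interval columns are selected by index.

The synthetic generator emulates labeled cohorts of scalar series with
controllable regularity so the full pipeline is testable without any
download: harmonic (sinusoid + Gaussian noise), AR(1), and logistic-map
families span the regular-to-chaotic axis the complexity statistic is
meant to resolve.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabeledSeriesTable",
    "GaitRecord",
    "ClassSpec",
    "SyntheticCohortSpec",
    "read_labeled_series",
    "read_gait_record",
    "generate_synthetic_cohorts",
    "write_results",
    "DEFAULT_TWO_CLASS_SPEC",
]

# cohort inference from gait database filename prefixes
_GAIT_PREFIXES = {"control": "HC", "park": "PD", "hunt": "HD", "als": "ALS"}


@dataclass
class LabeledSeriesTable:
    """Parsed (label, series) records plus provenance."""

    records: list  # list of (label, ndarray)
    source: str = ""

    @property
    def labels(self) -> list:
        return [lab for lab, _ in self.records]

    def class_counts(self) -> dict:
        counts: dict = {}
        for lab, _ in self.records:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def by_class(self) -> dict:
        out: dict = {}
        for lab, series in self.records:
            out.setdefault(lab, []).append(series)
        return out


@dataclass
class GaitRecord:
    """Raw left/right swing-interval series (seconds) for one subject."""

    lsi: np.ndarray
    rsi: np.ndarray
    cohort: str
    subject: str


def read_labeled_series(
    path,
    delimiter: str | None = None,
    class_names=None,
    label_map: dict | None = None,
) -> LabeledSeriesTable:
    """Read a label-prefixed delimited series table.

    Each line is ``label <sep> v1 <sep> v2 ...``. The delimiter is
    auto-detected (comma, tab, or any whitespace) unless given.
    ``label_map`` renames raw labels (e.g. the archive's numeric class
    codes) to class names; with ``class_names`` supplied, labels outside
    it raise a parse error.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if delimiter is not None:
                fields = line.split(delimiter)
            elif "," in line:
                fields = line.split(",")
            elif "\t" in line:
                fields = line.split("\t")
            else:
                fields = line.split()
            fields = [f for f in (f.strip() for f in fields) if f]
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: record has no series values")
            label = fields[0]
            # archives commonly store numeric class codes; keep them as-is
            if label.replace(".", "", 1).replace("-", "", 1).isdigit():
                label = str(int(float(label)))
            if label_map is not None:
                label = label_map.get(label, label)
            if class_names is not None and label not in class_names:
                raise ValueError(f"{path}:{lineno}: unknown class label {label!r}")
            try:
                values = np.array([float(f) for f in fields[1:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({err})") from err
            records.append((label, values))
    lengths = {len(v) for _, v in records}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged rows; series lengths {sorted(lengths)}")
    return LabeledSeriesTable(records, source=str(path))


def read_gait_record(
    path,
    column_map: dict | None = None,
    cohort: str | None = None,
) -> GaitRecord:
    """Read one whitespace-delimited gait record.

    ``column_map`` names the 0-based columns holding the left and right
    swing intervals, e.g. ``{"lsi": 3, "rsi": 4}``. The cohort is taken
    from ``cohort`` if given, else inferred from the filename prefix
    (control/park/hunt/als).
    """
    path = Path(path)
    column_map = column_map or {"lsi": 3, "rsi": 4}
    data = np.loadtxt(path, ndmin=2)
    for key in ("lsi", "rsi"):
        if key not in column_map:
            raise ValueError(f"{path}: column_map missing {key!r}")
        if not 0 <= column_map[key] < data.shape[1]:
            raise ValueError(
                f"{path}: column {column_map[key]} for {key!r} out of range "
                f"(file has {data.shape[1]} columns)"
            )
    if cohort is None:
        stem = path.stem.lower()
        for prefix, name in _GAIT_PREFIXES.items():
            if stem.startswith(prefix):
                cohort = name
                break
        else:
            raise ValueError(
                f"{path}: cannot infer cohort from filename; pass cohort= or a manifest"
            )
    return GaitRecord(
        lsi=data[:, column_map["lsi"]],
        rsi=data[:, column_map["rsi"]],
        cohort=cohort,
        subject=path.stem,
    )


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic class: a generator family with its parameters.

    family 'harmonic': sinusoid of the given period plus Gaussian noise
    (noise_sd in units of the unit-amplitude sinusoid); 'ar1': stationary
    AR(1) with coefficient ``ar_coeff`` and unit innovations; 'logistic':
    the logistic map x -> rate*x*(1-x) (chaotic for rate near 4).
    """

    family: str = "harmonic"
    noise_sd: float = 0.05
    period: float = 60.0
    ar_coeff: float = 0.8
    rate: float = 3.9
    count: int = 30
    length: int = 900

    def __post_init__(self) -> None:
        if self.family not in ("harmonic", "ar1", "logistic"):
            raise ValueError(f"unknown generator family {self.family!r}")
        if self.count < 1 or self.length < 2:
            raise ValueError("count must be >= 1 and length >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Labeled synthetic cohorts: {class label: ClassSpec} plus a seed."""

    classes: dict = field(
        default_factory=lambda: dict(DEFAULT_TWO_CLASS_SPEC)
    )
    seed: int = 0


#: Two cohorts differing only in noise level around the same sinusoid:
#: a near-regular class and a noise-dominated one, the desk-scale analogue
#: of a wild-type vs mutant contrast.
DEFAULT_TWO_CLASS_SPEC = {
    "regular": ClassSpec(family="harmonic", noise_sd=0.05, count=30, length=900),
    "irregular": ClassSpec(family="harmonic", noise_sd=0.5, count=30, length=900),
}


def _generate_one(spec: ClassSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.length
    if spec.family == "harmonic":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        clean = np.sin(2 * np.pi * t / spec.period + phase)
        return clean + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.family == "ar1":
        x = np.empty(n)
        x[0] = rng.normal(0.0, 1.0 / np.sqrt(1.0 - spec.ar_coeff**2))
        eps = rng.normal(0.0, 1.0, size=n - 1)
        for i in range(1, n):
            x[i] = spec.ar_coeff * x[i - 1] + eps[i - 1]
        return x
    # logistic map, discarding a transient so the orbit sits on the attractor
    x = rng.uniform(0.05, 0.95)
    for _ in range(100):
        x = spec.rate * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        x = spec.rate * x * (1.0 - x)
        out[i] = x
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=n)
    return out


def generate_synthetic_cohorts(spec: SyntheticCohortSpec) -> LabeledSeriesTable:
    """Seeded, reproducible synthetic cohorts (pure function of spec + seed)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for label in sorted(spec.classes):
        cls = spec.classes[label]
        for _ in range(cls.count):
            records.append((label, _generate_one(cls, rng)))
    return LabeledSeriesTable(records, source=f"synthetic(seed={spec.seed})")


def write_results(
    out_dir,
    records=None,
    summaries=None,
    trees=None,
    manifest: dict | None = None,
) -> dict:
    """Write per-series results, cohort summaries, trees, and a run manifest.

    records: iterable of dicts with keys series_id, label, statistic, value
    (plus optional extras such as size_trajectory); summaries: iterable of
    CohortSummary; trees: {name: Dendrogram}. Returns {kind: path}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    if records is not None:
        path = out_dir / "series_results.csv"
        rows = list(records)
        fields = ["series_id", "label", "statistic", "value"]
        extra = sorted({k for r in rows for k in r} - set(fields))
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields + extra)
            writer.writeheader()
            for row in rows:
                row = dict(row)
                if np.isinf(row.get("value", 0.0)):
                    row["value"] = "inf"
                writer.writerow(row)
        written["series"] = path

    if summaries is not None:
        path = out_dir / "cohort_summaries.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["label", "n", "mean", "sd", "p_value",
                 "ci95_lower", "ci95_upper", "ci99_lower", "ci99_upper"]
            )
            for s in summaries:
                writer.writerow(
                    [s.label, s.n, s.mean, s.sd, s.p_value,
                     s.ci95[0], s.ci95[1], s.ci99[0], s.ci99[1]]
                )
        written["summaries"] = path

    for name, tree in (trees or {}).items():
        path = out_dir / f"{name}.nwk"
        path.write_text(tree.newick + "\n")
        written[f"tree:{name}"] = path

    if manifest is not None:
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=_jsonable) + "\n")
        written["manifest"] = path

    return written


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
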