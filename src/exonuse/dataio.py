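"""Domain types, TSV readers/writers and structural validation for
probe-level exon-array data.

The on-disk dialect is deliberately plain: UTF-8 TSV, ``.`` decimal
separator, no quoting.  A probe table carries five annotation columns
(``probe_id``, ``probeset_id``, ``transcript_id``, ``probeset_order``,
``cross_hybridizing``) followed by one intensity column per sample; the
sample sheet carries ``sample_id``, ``treatment``, ``time_h``,
``replicate``.  Vendor binary formats (CEL) and annotation databases are
out of scope — the caller supplies the probe→probeset→transcript map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("untreated", "vehicle", "kainate")
TIMEPOINTS = (1, 4, 8)
#: condition labels used by the splice detectors: controls (untreated and
#: vehicle, any collection time) are pooled at time 0.
CONDITIONS = ("control", "KA1", "KA4", "KA8")

ANNOTATION_COLUMNS = (
    "probe_id",
    "probeset_id",
    "transcript_id",
    "probeset_order",
    "cross_hybridizing",
)
SHEET_COLUMNS = ("sample_id", "treatment", "time_h", "replicate")


class FormatError(ValueError):
    """Malformed file structure (header, column set)."""


class ParseError(ValueError):
    """Unparseable cell value, with row/column context."""


class IntegrityError(ValueError):
    """Violated uniqueness or referential invariant."""


class DesignError(ValueError):
    """Sample design violating the treatment/time contract."""


@dataclass(frozen=True)
class SampleDesign:
    """One array: which animal group and collection time it profiles."""

    sample_id: str
    treatment: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ParseError(f"unknown treatment {self.treatment!r}")
        if self.treatment == "untreated" and self.time_h != 0:
            raise DesignError(
                f"untreated sample {self.sample_id!r} must have time_h=0, "
                f"got {self.time_h}"
            )
        if self.treatment != "untreated" and self.time_h not in TIMEPOINTS:
            raise DesignError(
                f"{self.treatment} sample {self.sample_id!r} must have "
                f"time_h in {TIMEPOINTS}, got {self.time_h}"
            )
        if self.replicate < 1:
            raise DesignError(f"replicate must be positive for {self.sample_id!r}")

    @property
    def condition(self) -> str:
        """Pooled condition label: controls at 0 h, kainate by timepoint."""
        if self.treatment == "kainate":
            return f"KA{self.time_h}"
        return "control"


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    probeset_id: str
    transcript_id: str
    probeset_order: int
    cross_hybridizing: bool


@dataclass
class ValidationReport:
    n_probes: int
    n_probesets: int
    n_transcripts: int
    n_samples: int
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ExonArrayDataset:
    """Probe×sample intensity matrix bound to annotations and a design.

    ``intensities`` is indexed by probe_id with one column per sample_id,
    column order matching ``design`` order.  ``scale`` is ``"linear"``
    (strictly positive values) or ``"log2"``.
    """

    annotation: pd.DataFrame
    design: pd.DataFrame
    intensities: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")

    @property
    def n_probes(self) -> int:
        return len(self.annotation)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def conditions(self) -> pd.Series:
        """Pooled condition label per sample (index sample_id)."""
        lab = np.where(
            self.design["treatment"].to_numpy() == "kainate",
            "KA" + self.design["time_h"].astype(str),
            "control",
        )
        return pd.Series(lab, index=self.design["sample_id"].to_numpy(), name="condition")

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExonArrayDataset":
        keep = self.annotation["probe_id"].isin(set(probe_ids))
        ann = self.annotation.loc[keep].reset_index(drop=True)
        return ExonArrayDataset(
            annotation=ann,
            design=self.design.copy(),
            intensities=self.intensities.loc[ann["probe_id"]],
            scale=self.scale,
        )


def design_frame(designs: Iterable[SampleDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.sample_id, d.treatment, d.time_h, d.replicate) for d in designs],
        columns=list(SHEET_COLUMNS),
    )


def load_sample_sheet(path: str | Path) -> list[SampleDesign]:
    """Read a sample sheet TSV into validated SampleDesign records.

    Treatment tokens are normalized case-insensitively; untreated samples
    must sit at time 0 and treated samples at 1/4/8 h.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    designs: list[SampleDesign] = []
    for i, row in df.iterrows():
        treatment = str(row["treatment"]).strip().lower()
        if treatment not in TREATMENTS:
            raise ParseError(
                f"row {i}: unknown treatment token {row['treatment']!r}"
            )
        try:
            time_h = int(row["time_h"])
            replicate = int(row["replicate"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: non-integer time_h/replicate") from exc
        designs.append(
            SampleDesign(str(row["sample_id"]), treatment, time_h, replicate)
        )
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise IntegrityError(f"duplicate sample_id values: {dup}")
    return designs


def load_probe_table(
    path: str | Path,
    scale: str,
    design: Sequence[SampleDesign] | pd.DataFrame | None = None,
) -> ExonArrayDataset:
    """Read a probe table TSV; columns are reordered to the design order.

    When ``design`` is given, sample columns in the file must be exactly
    the design's sample_ids (any order); unknown or missing columns are
    errors, never silently dropped or imputed.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ANNOTATION_COLUMNS[:3]})
    got = tuple(df.columns[: len(ANNOTATION_COLUMNS)])
    if got != ANNOTATION_COLUMNS:
        raise FormatError(
            f"probe table must start with columns {ANNOTATION_COLUMNS}, got {got}"
        )
    ann = df[list(ANNOTATION_COLUMNS)].copy()
    dup = ann["probe_id"][ann["probe_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate probe_id values: {sorted(set(dup))}")
    ann["probeset_order"] = ann["probeset_order"].astype(int)
    ann["cross_hybridizing"] = _parse_bool_column(ann["cross_hybridizing"])

    sample_cols = list(df.columns[len(ANNOTATION_COLUMNS):])
    inten = df[sample_cols].copy()
    for col in sample_cols:
        vals = pd.to_numeric(inten[col], errors="coerce")
        bad = vals.isna() & inten[col].notna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric intensity at row {r}, column {col!r}: "
                f"{inten[col].iloc[r]!r}"
            )
        inten[col] = vals.astype(float)
    inten.index = ann["probe_id"].to_numpy()

    if design is not None:
        ddf = design if isinstance(design, pd.DataFrame) else design_frame(design)
        want = list(ddf["sample_id"])
        unknown = [c for c in sample_cols if c not in want]
        missing = [s for s in want if s not in sample_cols]
        if unknown:
            raise FormatError(f"unknown sample columns {unknown}")
        if missing:
            raise FormatError(f"missing sample columns {missing}")
        inten = inten[want]
        ddf = ddf.reset_index(drop=True)
    else:
        ddf = pd.DataFrame(
            {
                "sample_id": sample_cols,
                "treatment": "untreated",
                "time_h": 0,
                "replicate": range(1, len(sample_cols) + 1),
            }
        )
    return ExonArrayDataset(annotation=ann, design=ddf, intensities=inten, scale=scale)


def _parse_bool_column(col: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        r = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ParseError(f"unparseable boolean at row {r}: {col.iloc[r]!r}")
    return out.astype(bool)


def validate_dataset(ds: ExonArrayDataset) -> ValidationReport:
    """Structural validation; violations are data, not exceptions."""
    ann, design, X = ds.annotation, ds.design, ds.intensities
    report = ValidationReport(
        n_probes=len(ann),
        n_probesets=ann["probeset_id"].nunique(),
        n_transcripts=ann["transcript_id"].nunique(),
        n_samples=len(design),
    )
    v = report.violations
    if len(X) != len(ann):
        v.append(("SHAPE", f"{len(X)} intensity rows vs {len(ann)} annotations"))
    if X.shape[1] != len(design):
        v.append(("SHAPE", f"{X.shape[1]} intensity columns vs {len(design)} samples"))
    elif list(X.columns) != list(design["sample_id"]):
        v.append(("COLUMN_ORDER", "intensity columns do not match design order"))
    dup = ann["probe_id"][ann["probe_id"].duplicated()]
    if len(dup):
        v.append(("DUP_PROBE", f"duplicate probe_id: {sorted(set(dup))}"))
    dups = design["sample_id"][design["sample_id"].duplicated()]
    if len(dups):
        v.append(("DUP_SAMPLE", f"duplicate sample_id: {sorted(set(dups))}"))
    # probeset -> exactly one transcript
    multi = ann.groupby("probeset_id")["transcript_id"].nunique()
    for ps in multi.index[multi > 1]:
        v.append(("MULTI_TRANSCRIPT", f"probeset {ps} maps to multiple transcripts"))
    # probeset_order total order within transcript
    order = ann.drop_duplicates(["transcript_id", "probeset_id"])
    tied = order.groupby("transcript_id")["probeset_order"].apply(
        lambda s: s.duplicated().any()
    )
    for tid in tied.index[tied]:
        v.append(("ORDER_TIE", f"transcript {tid} has tied probeset_order values"))
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        v.append(("NAN_INTENSITY", f"{int(np.isnan(vals).sum())} missing intensities"))
    if ds.scale == "linear" and vals.size and np.nanmin(vals) <= 0:
        v.append(("NEG_INTENSITY", "non-positive intensity on linear scale"))
    for d in design.itertuples():
        try:
            SampleDesign(d.sample_id, d.treatment, int(d.time_h), int(d.replicate))
        except (ParseError, DesignError) as exc:
            v.append(("DESIGN", str(exc)))
    return report


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with lossless float round-trips.

    Floats are serialized with %.10g (>= 10 significant digits), which
    round-trips through the readers within 1e-9 relative error.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_probe_table(ds: ExonArrayDataset, path: str | Path) -> Path:
    """Write a dataset back to the probe-table TSV schema."""
    out = ds.annotation.copy()
    for col in ds.intensities.columns:
        out[col] = ds.intensities[col].to_numpy()
    return write_table(out, path)


def write_sample_sheet(design: pd.DataFrame | Sequence[SampleDesign], path: str | Path) -> Path:
    ddf = design if isinstance(design, pd.DataFrame) else design_frame(design)
    return write_table(ddf, path)
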