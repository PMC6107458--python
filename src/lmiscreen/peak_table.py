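"""Peak tables, cohort manifests and the transformations applied before screening.

The quantitative unit of the whole analysis is the *peak table*: an ions x
samples matrix of non-negative LC-MS peak areas, each ion identified by its
mass-to-charge ratio (m/z) and retention time (RT, minutes).  Screening is
performed on common-logarithmic areas; a peak area of exactly 0 is set to 1
before taking logarithms, so missing peaks map to a log-area of 0.0.

Total-area-sums normalization rescales every sample column by one scalar so
that all samples have the same summed (raw) peak area; the target total is the
mean of the original column totals, which preserves the overall magnitude of
the table.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_LABELS",
    "IonID",
    "PeakTable",
    "CohortManifest",
    "Comparison",
    "STANDARD_COMPARISONS",
    "read_peak_table",
    "write_peak_table",
    "read_manifest",
    "write_manifest",
    "log_transform",
    "normalize_total_area",
]

#: Group labels used by the cohort design: two target cancers (pancreatic and
#: biliary tract), two positive-control cancers (colorectal, ovarian), healthy
#: controls, and the two pre-malignant high-risk groups.
GROUP_LABELS = ("PC", "BTC", "CRC", "OVC", "control", "PC_HRG", "BTC_HRG")


class IonID(NamedTuple):
    """A low-mass ion, identified by the (m/z, RT) pair.

    m/z alone is not an identity: distinct ions can share a mass value at
    different retention times.
    """

    mz: float
    rt: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.mz:g}@{self.rt:g}min"


@dataclass
class PeakTable:
    """Ions x samples matrix of peak areas.

    Parameters
    ----------
    ions
        Ordered ion identities; (m/z, RT) pairs must be unique.
    samples
        Ordered, unique sample identifiers.  Sample identity is carried by
        name, never by position, so manifest joins are order-independent.
    areas
        ``(len(ions), len(samples))`` float matrix.  All entries must be
        non-negative when ``scale == "raw"``.
    scale
        ``"raw"`` (areas as exported by peak finding) or ``"log10"``.
    provenance
        Free-form acquisition / peak-finding metadata carried along unchanged.
    """

    ions: list[IonID]
    samples: list[str]
    areas: np.ndarray
    scale: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ions = [IonID(float(mz), float(rt)) for mz, rt in self.ions]
        self.samples = [str(s) for s in self.samples]
        self.areas = np.asarray(self.areas, dtype=float).reshape(
            len(self.ions), len(self.samples)
        )
        if self.scale not in ("raw", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if len(set(self.ions)) != len(self.ions):
            raise ValueError("(mz, rt) pairs must be unique")
        for ion in self.ions:
            if not ion.mz > 0:
                raise ValueError(f"ion {ion} has non-positive m/z")
            if ion.rt < 0:
                raise ValueError(f"ion {ion} has negative RT")
        if not np.all(np.isfinite(self.areas)):
            raise ValueError("peak areas must be finite")
        if self.scale == "raw" and np.any(self.areas < 0):
            i, j = np.argwhere(self.areas < 0)[0]
            raise ValueError(
                f"negative area at ion {self.ions[i]}, sample {self.samples[j]!r}"
            )

    @property
    def n_ions(self) -> int:
        return len(self.ions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def ion_index(self, ion: IonID) -> int:
        try:
            return self.ions.index(IonID(*ion))
        except ValueError:
            raise KeyError(f"ion {ion} not in table") from None

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return np.array([lookup[n] for n in names], dtype=np.intp)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, columns=self.samples)
        df.insert(0, "rt", [i.rt for i in self.ions])
        df.insert(0, "mz", [i.mz for i in self.ions])
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return (
            self.ions == other.ions
            and self.samples == other.samples
            and self.scale == other.scale
            and self.areas.shape == other.areas.shape
            and bool(np.array_equal(self.areas, other.areas))
            and self.provenance == other.provenance
        )


@dataclass(frozen=True)
class Comparison:
    """A two-class contrast: positive-class groups vs negative-class groups."""

    positive_groups: frozenset[str]
    negative_groups: frozenset[str]
    name: str = ""

    def __init__(
        self,
        positive_groups: Iterable[str],
        negative_groups: Iterable[str],
        name: str = "",
    ) -> None:
        object.__setattr__(self, "positive_groups", frozenset(positive_groups))
        object.__setattr__(self, "negative_groups", frozenset(negative_groups))
        if not self.positive_groups or not self.negative_groups:
            raise ValueError("both comparison classes must be non-empty")
        overlap = self.positive_groups & self.negative_groups
        if overlap:
            raise ValueError(f"groups on both sides of comparison: {sorted(overlap)}")
        if not name:
            name = "+".join(sorted(self.positive_groups)) + "_vs_" + "+".join(
                sorted(self.negative_groups)
            )
        object.__setattr__(self, "name", name)


#: The three contrasts of the study design.
STANDARD_COMPARISONS = {
    "cancer_vs_noncancer": Comparison(
        {"PC", "BTC"}, {"control", "CRC", "OVC"}, "cancer_vs_noncancer"
    ),
    "pc_vs_btc": Comparison({"PC"}, {"BTC"}, "pc_vs_btc"),
    "cancer_vs_high_risk": Comparison(
        {"PC", "BTC"}, {"PC_HRG", "BTC_HRG"}, "cancer_vs_high_risk"
    ),
}


@dataclass
class CohortManifest:
    """Mapping from sample identifier to group label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, groups: Iterable[str]) -> list[str]:
        gset = set(groups)
        return [s for s, g in self.assignments.items() if g in gset]

    def class_labels(
        self, table: PeakTable, comparison: Comparison
    ) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the positive and negative class samples.

        Samples in neither class are excluded; a sample present in the table
        but absent from the manifest is an error only if its group is needed.
        """
        pos = [s for s in table.samples
               if self.assignments.get(s) in comparison.positive_groups]
        neg = [s for s in table.samples
               if self.assignments.get(s) in comparison.negative_groups]
        if not pos or not neg:
            raise ValueError(
                f"comparison {comparison.name!r} selects {len(pos)} positive and "
                f"{len(neg)} negative samples in the table"
            )
        return table.sample_indices(pos), table.sample_indices(neg)


# ---------------------------------------------------------------------------
# File formats: TSV peak table with '# key=value' header comments, TSV manifest
# ---------------------------------------------------------------------------


def _parse_header_comments(lines: list[str]) -> tuple[str, dict]:
    scale = "raw"
    provenance: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if body.startswith("scale="):
            scale = body[len("scale="):].strip()
        elif body.startswith("provenance="):
            provenance = json.loads(body[len("provenance="):])
    return scale, provenance


def read_peak_table(path, dialect: str = "tsv") -> PeakTable:
    """Read a peak table from delimited text.

    The file holds one row per ion: columns ``mz``, ``rt``, then one peak-area
    column per sample.  Optional leading comment lines carry the scale marker
    (``# scale=raw|log10``) and provenance (``# provenance={...}`` JSON).

    ``dialect`` is ``"tsv"`` (default) or ``"csv"``.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().splitlines()
    comments = [ln for ln in raw_lines if ln.startswith("#")]
    body = [ln for ln in raw_lines if not ln.startswith("#") and ln.strip() != ""]
    if not body:
        raise ValueError(f"{path}: no header row")
    scale, provenance = _parse_header_comments(comments)
    header = body[0].split(sep)
    if header[:2] != ["mz", "rt"]:
        raise ValueError(f"{path}: header must start with 'mz', 'rt' (got {header[:2]})")
    sample_names = header[2:]
    if len(set(sample_names)) != len(sample_names):
        raise ValueError(f"{path}: duplicate sample columns")
    df = pd.read_csv(
        io.StringIO("\n".join(body)), sep=sep, header=0, names=header, dtype=str,
        keep_default_na=False, na_filter=False,
    )
    ions: list[IonID] = []
    columns = {}
    for col in header:
        # float() is correctly rounded, so write -> read round-trips exactly
        # (pd.to_numeric's fast path is not).
        cells = df[col].tolist()
        values = np.empty(len(cells), dtype=float)
        for r, cell in enumerate(cells):
            try:
                values[r] = float(cell)
            except (TypeError, ValueError):
                values[r] = np.nan
            if not np.isfinite(values[r]):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"data row {r + 1}"
                )
        columns[col] = values
    for r, (mz, rt) in enumerate(zip(columns["mz"], columns["rt"])):
        ions.append(IonID(mz, rt))
    areas = (
        np.column_stack([columns[s] for s in sample_names])
        if sample_names
        else np.empty((len(ions), 0))
    )
    if scale == "raw" and areas.size and np.any(areas < 0):
        i, j = np.argwhere(areas < 0)[0]
        raise ValueError(
            f"{path}: negative area {areas[i, j]} at ion "
            f"({ions[i].mz}, {ions[i].rt}), sample {sample_names[j]!r}"
        )
    if len(set(ions)) != len(ions):
        dupes = pd.Series(ions)[pd.Series(ions).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate (mz, rt) pair {tuple(dupes)}")
    return PeakTable(ions, list(sample_names), areas, scale=scale, provenance=provenance)


def write_peak_table(table: PeakTable, path, dialect: str = "tsv") -> None:
    """Write a peak table re-readably; the scale marker is always emitted so
    raw and log10 tables cannot be confused."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# scale={table.scale}\n")
        if table.provenance:
            fh.write(f"# provenance={json.dumps(table.provenance, sort_keys=True)}\n")
        fh.write(sep.join(["mz", "rt", *table.samples]) + "\n")
        for i, ion in enumerate(table.ions):
            cells = [repr(ion.mz), repr(ion.rt)]
            cells += [repr(float(a)) for a in table.areas[i]]
            fh.write(sep.join(cells) + "\n")


def read_manifest(path) -> CohortManifest:
    """Read a sample manifest: TSV with columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: manifest columns must be 'sample', 'group'")
    if df["sample"].duplicated().any():
        dupe = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: sample {dupe!r} listed more than once")
    return CohortManifest(dict(zip(df["sample"], df["group"])))


def write_manifest(manifest: CohortManifest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s, g in manifest.assignments.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def log_transform(table: PeakTable) -> PeakTable:
    """Common-logarithm transform with the zero rule.

    A peak area of exactly 0 is set to 1 before taking log10, so it maps to
    0.0.  The substitution applies *only* to exact zeros: areas in (0, 1)
    pass through log10 unchanged and become negative.
    """
    if table.scale != "raw":
        raise ValueError("table is already log10 scale")
    areas = table.areas.copy()
    areas[areas == 0.0] = 1.0
    with np.errstate(divide="ignore"):
        logged = np.log10(areas)
    return PeakTable(
        list(table.ions),
        list(table.samples),
        logged,
        scale="log10",
        provenance=dict(table.provenance),
    )


def normalize_total_area(table: PeakTable) -> PeakTable:
    """Total-area-sums normalization on the raw scale.

    Each sample column is multiplied by one scalar so that every column sums
    to the mean of the original column totals; relative areas within a sample
    are preserved.  Normalization precedes the log transform.
    """
    if table.scale != "raw":
        raise ValueError("normalization is defined on raw-scale areas")
    totals = table.areas.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(
            f"sample {table.samples[j]!r} has zero total area; scaling undefined"
        )
    target = totals.mean()
    scaled = table.areas * (target / totals)[np.newaxis, :]
    return PeakTable(
        list(table.ions),
        list(table.samples),
        scaled,
        scale="raw",
        provenance=dict(table.provenance),
    )
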