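"""Core data model and TSV readers/writers.

Read counts per feature per library are the canonical on-disk input of the
whole pipeline; abundance percentages are always derived from them.  A
separate "percentage mode" loader (:func:`read_abundance_table`) accepts a
printed percentage matrix directly, so published abundance tables can be used
as golden inputs even though the underlying raw counts were never printed.

Missing cells in a percentage matrix ("-" / "–") load as *not detected*,
which is distinct from an explicit zero: detection gates which libraries
enter the rank statistics downstream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Library",
    "CountTable",
    "VirusMeta",
    "Config",
    "FormatError",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "read_virus_meta",
    "write_virus_meta",
    "read_abundance_table",
    "read_config",
]

STAGES = ("larvae", "pupa", "adult")

#: strings treated as "not detected" in percentage-mode tables
NOT_DETECTED = {"-", "–", "—", "NA", ""}


class FormatError(ValueError):
    """Malformed input file (missing columns, bad header)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


@dataclass(frozen=True)
class Library:
    """One sequencing library and its size.

    ``total_reads`` is the denominator of every abundance percentage: the
    total number of reads in the library (post-trimming), not the non-host
    subset.
    """

    library_id: str
    total_reads: int
    accession: str = ""
    stage: str = "adult"
    tissue: str = "whole_body"
    origin: str = ""

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValidationError(
                f"library {self.library_id!r}: total_reads must be >= 0"
            )
        if self.stage not in STAGES:
            raise ValidationError(
                f"library {self.library_id!r}: stage {self.stage!r} not in {STAGES}"
            )


@dataclass
class CountTable:
    """Read counts per (feature, library).

    Absent pairs mean zero reads (not detected).  ``feature_kind`` maps each
    feature to ``"virus_segment"`` or ``"housekeeping"``.
    """

    libraries: list[Library]
    counts: dict[tuple[str, str], int]
    feature_kind: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        lib_ids = [lib.library_id for lib in self.libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValidationError("duplicate library_id")
        known = set(lib_ids)
        per_lib_sum: dict[str, int] = {l: 0 for l in lib_ids}
        for (feat, lib), n in self.counts.items():
            if lib not in known:
                raise ValidationError(f"count references unknown library {lib!r}")
            if feat not in self.feature_kind:
                raise ValidationError(f"count references unknown feature {feat!r}")
            if n < 0:
                raise ValidationError(f"negative read count for ({feat!r}, {lib!r})")
            per_lib_sum[lib] += n
        for lib in self.libraries:
            if per_lib_sum[lib.library_id] > lib.total_reads:
                raise ValidationError(
                    f"library {lib.library_id!r}: feature counts "
                    f"({per_lib_sum[lib.library_id]}) exceed total_reads "
                    f"({lib.total_reads})"
                )
        bad = set(self.feature_kind.values()) - {"virus_segment", "housekeeping"}
        if bad:
            raise ValidationError(f"unknown feature kinds: {sorted(bad)}")

    # -- accessors --------------------------------------------------------
    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    @property
    def feature_ids(self) -> list[str]:
        return sorted(self.feature_kind)

    def library(self, library_id: str) -> Library:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)

    def count(self, feature_id: str, library_id: str) -> int:
        return self.counts.get((feature_id, library_id), 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-form counts, one row per recorded (feature, library) pair."""
        rows = [
            {
                "library_id": lib,
                "feature_id": feat,
                "feature_kind": self.feature_kind[feat],
                "reads": n,
            }
            for (feat, lib), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["library_id", "feature_id", "feature_kind", "reads"])


@dataclass(frozen=True)
class VirusMeta:
    """Per-virus metadata feeding the host-association criteria.

    ``complete_cds`` (complete coding regions recovered) and ``insect_phylo``
    (phylogenetically close to another insect virus) are inputs, not
    computed: phylogenetics is outside this pipeline.
    """

    virus_id: str
    segment_ids: tuple[str, ...]
    complete_cds: bool
    insect_phylo: bool

    def __post_init__(self) -> None:
        if not self.segment_ids:
            raise ValidationError(f"virus {self.virus_id!r}: empty segment list")
        if len(set(self.segment_ids)) != len(self.segment_ids):
            raise ValidationError(f"virus {self.virus_id!r}: duplicate segment ids")


def validate_virus_set(viruses: Iterable[VirusMeta]) -> None:
    """Segments must be disjoint across viruses."""
    seen: dict[str, str] = {}
    for v in viruses:
        for seg in v.segment_ids:
            if seg in seen:
                raise ValidationError(
                    f"segment {seg!r} claimed by both {seen[seg]!r} and {v.virus_id!r}"
                )
            seen[seg] = v.virus_id


@dataclass
class Config:
    """Pipeline configuration with the study defaults.

    abundance_threshold_percent
        Minimum whole-virus abundance (percent of library reads) for the
        detection-level criterion; the comparison is strict (> threshold).
    alpha
        Significance level of the Kruskal-Wallis test and rank-LSD post hoc.
    log_transform
        Log-transform abundances before testing.  Rank statistics are
        invariant under any strictly monotone transform, so this cannot
        change the outcome; kept for parity with common practice and for
        future parametric options.
    rule
        Host-call rule: ``"cds_plus_2"`` (complete CDS mandatory plus at
        least two of the remaining criteria) or ``"at_least_k"`` with ``k``.
    """

    abundance_threshold_percent: float = 0.01
    alpha: float = 0.05
    log_transform: bool = True
    rule: str = "cds_plus_2"
    k: int = 2
    threshold_aggregation: str = "median"  # median | any | per_library
    denominator: str = "total"  # total | nonhost (nonhost requires host counts)
    motif_five: str = "ACACAAAGU"
    motif_three: str = "ACUUUGUGU"
    max_mismatch: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.abundance_threshold_percent > 0:
            raise ValidationError("abundance_threshold_percent must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.rule not in ("cds_plus_2", "at_least_k"):
            raise ValidationError(f"unknown rule {self.rule!r}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_COUNT_COLS = ["library_id", "feature_id", "feature_kind", "reads"]
_LIB_COLS = ["library_id", "total_reads"]
_META_COLS = ["virus_id", "segment_ids", "complete_cds", "insect_phylo"]


def _require_columns(df: pd.DataFrame, cols: list[str], path: object) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_count_table(counts_path: str | Path, libraries_path: str | Path) -> CountTable:
    """Read a long-form counts TSV plus its companion library table.

    The counts file has columns ``library_id, feature_id, feature_kind,
    reads``; the library file has ``library_id, total_reads`` and optionally
    ``accession, stage, tissue, origin``.  Duplicate (feature, library) rows
    are an error rather than being summed.
    """
    cdf = pd.read_csv(counts_path, sep="\t", dtype={"library_id": str, "feature_id": str})
    ldf = pd.read_csv(libraries_path, sep="\t", dtype={"library_id": str})
    _require_columns(cdf, _COUNT_COLS, counts_path)
    _require_columns(ldf, _LIB_COLS, libraries_path)

    dup = cdf.duplicated(subset=["feature_id", "library_id"])
    if dup.any():
        pairs = cdf.loc[dup, ["feature_id", "library_id"]].values.tolist()
        raise ValidationError(f"{counts_path}: duplicate (feature, library) rows: {pairs}")

    libraries = []
    for row in ldf.itertuples(index=False):
        d = row._asdict()
        libraries.append(
            Library(
                library_id=d["library_id"],
                total_reads=int(d["total_reads"]),
                accession=str(d.get("accession", "") or ""),
                stage=str(d.get("stage", "adult") or "adult"),
                tissue=str(d.get("tissue", "whole_body") or "whole_body"),
                origin=str(d.get("origin", "") or ""),
            )
        )

    counts: dict[tuple[str, str], int] = {}
    kinds: dict[str, str] = {}
    for row in cdf.itertuples(index=False):
        n = int(row.reads)
        if n < 0:
            raise ValidationError(
                f"{counts_path}: negative reads for ({row.feature_id}, {row.library_id})"
            )
        counts[(row.feature_id, row.library_id)] = n
        prev = kinds.setdefault(row.feature_id, row.feature_kind)
        if prev != row.feature_kind:
            raise ValidationError(
                f"{counts_path}: feature {row.feature_id!r} has conflicting kinds"
            )
    return CountTable(libraries=libraries, counts=counts, feature_kind=kinds)


def write_count_table(
    table: CountTable, counts_path: str | Path, libraries_path: str | Path
) -> None:
    table.to_frame().to_csv(counts_path, sep="\t", index=False)
    ldf = pd.DataFrame([dataclasses.asdict(lib) for lib in table.libraries])
    ldf = ldf[["library_id", "total_reads", "accession", "stage", "tissue", "origin"]]
    ldf.to_csv(libraries_path, sep="\t", index=False)


def read_virus_meta(path: str | Path) -> list[VirusMeta]:
    """Read virus metadata: ``virus_id, segment_ids, complete_cds, insect_phylo``.

    ``segment_ids`` is comma-joined; booleans accept true/false/1/0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _META_COLS, path)

    def as_bool(x: str) -> bool:
        s = str(x).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise FormatError(f"{path}: cannot parse boolean {x!r}")

    viruses = []
    for row in df.itertuples(index=False):
        segs = tuple(s.strip() for s in str(row.segment_ids).split(",") if s.strip())
        viruses.append(
            VirusMeta(
                virus_id=row.virus_id,
                segment_ids=segs,
                complete_cds=as_bool(row.complete_cds),
                insect_phylo=as_bool(row.insect_phylo),
            )
        )
    validate_virus_set(viruses)
    return viruses


def write_virus_meta(viruses: Iterable[VirusMeta], path: str | Path) -> None:
    rows = [
        {
            "virus_id": v.virus_id,
            "segment_ids": ",".join(v.segment_ids),
            "complete_cds": v.complete_cds,
            "insect_phylo": v.insect_phylo,
        }
        for v in viruses
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path):
    """Percentage-mode loader: a features x libraries matrix of percentages.

    First column is ``feature_id``; remaining columns are library ids.  Cells
    holding "-"/"–" (or empty) load as not-detected.  Returns an
    :class:`virhost.abundance.AbundanceTable`.
    """
    from .abundance import AbundanceTable  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id'")
    values: dict[tuple[str, str], float] = {}
    detected: dict[tuple[str, str], bool] = {}
    lib_ids = list(df.columns[1:])
    for row in df.itertuples(index=False):
        feat = row.feature_id
        for lib, cell in zip(lib_ids, row[1:]):
            s = "" if cell is None or (isinstance(cell, float) and math.isnan(cell)) else str(cell).strip()
            if s in NOT_DETECTED:
                detected[(feat, lib)] = False
            else:
                values[(feat, lib)] = float(s)
                detected[(feat, lib)] = True
    return AbundanceTable(
        values=values,
        detected=detected,
        feature_ids=list(df["feature_id"]),
        library_ids=lib_ids,
    )


def read_config(path: str | Path) -> Config:
    """Parse a flat ``key=value`` config file (decimal point, not locale)."""
    kwargs: dict[str, object] = {}
    fields = {f.name: f.type for f in dataclasses.fields(Config)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(Config(), key)
        if isinstance(current, bool):
            kwargs[key] = raw.lower() in ("true", "1", "yes")
        elif isinstance(current, int):
            kwargs[key] = int(raw)
        elif isinstance(current, float):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return Config(**kwargs)  # type: ignore[arg-type]
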