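"""Readers, writers and validated in-memory containers.

The canonical genotype dialect is a wide binary table: one row per accession,
one column per allele-locus, cells in {0, 1, NA}.  Allele-locus ids encode
the parent SSR marker and the amplified fragment size as
``"<marker>_<fragment>"`` (e.g. ``BNL1421_220``); the marker name is
recovered by splitting at the *last* underscore, since marker names may
themselves contain underscores but never a trailing ``_<digits>`` fragment
suffix of their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import DataError, FormatError, ParameterError, ParseError

DEFAULT_NA_TOKENS = ("NA", "-", "")

TRAITS = ("FL", "FS", "FM", "FU")


def split_locus_id(locus_id: str) -> tuple[str, str]:
    """Split an allele-locus id into (marker, fragment) at the last underscore.

    A locus id without an underscore is treated as a single-allele marker
    whose fragment label is empty.
    """
    marker, sep, fragment = locus_id.rpartition("_")
    if not sep:
        return locus_id, ""
    return marker, fragment


@dataclass
class SSRPanel:
    """Accessions x allele-loci presence/absence calls.

    ``calls`` is a float array: 1.0 band present, 0.0 absent, NaN missing.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accession_ids), len(self.locus_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.locus_ids)} loci"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise FormatError("duplicate accession ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus ids")
        valid = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 1.0)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise FormatError(
                f"call value {self.calls[i, j]!r} for accession "
                f"{self.accession_ids[i]!r} at locus {self.locus_ids[j]!r} is not 0/1/NA"
            )

    # -- derived structure ---------------------------------------------------

    @property
    def marker_of(self) -> dict[str, str]:
        return {l: split_locus_id(l)[0] for l in self.locus_ids}

    @property
    def marker_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.locus_ids:
            seen.setdefault(split_locus_id(l)[0])
        return list(seen)

    def loci_of(self, marker: str) -> list[str]:
        return [l for l in self.locus_ids if split_locus_id(l)[0] == marker]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    # -- views ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accession_ids, columns=self.locus_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SSRPanel":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_loci(self, loci: list[str]) -> "SSRPanel":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise DataError(f"loci not in panel: {missing[:5]}")
        idx = [pos[l] for l in loci]
        return SSRPanel(list(self.accession_ids), list(loci), self.calls[:, idx])

    def select_accessions(self, accessions: list[str]) -> "SSRPanel":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [pos[a] for a in accessions]
        return SSRPanel(list(accessions), list(self.locus_ids), self.calls[idx, :])

    def equals(self, other: "SSRPanel") -> bool:
        return (
            self.accession_ids == other.accession_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


@dataclass
class GeneticMap:
    """Allele-locus -> (chromosome 1..26, position in cM) assignments."""

    table: pd.DataFrame  # index locus, columns chromosome (int), position_cM (float)

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            dupes = t.index[t.index.duplicated()].tolist()
            raise FormatError(f"duplicate locus entries in map: {dupes[:5]}")
        chrom = t["chromosome"].to_numpy()
        pos = t["position_cM"].to_numpy(dtype=float)
        if not np.isfinite(pos).all() or (pos < 0).any():
            raise FormatError("map positions must be finite and non-negative")
        if ((chrom < 1) | (chrom > 26)).any():
            raise FormatError("chromosome outside 1..26")

    @property
    def loci(self) -> list[str]:
        return list(self.table.index)

    def is_placed(self, locus: str) -> bool:
        return locus in self.table.index

    def unplaced(self, loci: list[str]) -> list[str]:
        return [l for l in loci if not self.is_placed(l)]

    def chromosome(self, locus: str) -> int:
        return int(self.table.loc[locus, "chromosome"])

    def position(self, locus: str) -> float:
        return float(self.table.loc[locus, "position_cM"])

    def distance(self, locus_a: str, locus_b: str) -> float | None:
        """Map distance in cM, or None if unplaced or on different chromosomes."""
        if not (self.is_placed(locus_a) and self.is_placed(locus_b)):
            return None
        if self.chromosome(locus_a) != self.chromosome(locus_b):
            return None
        return abs(self.position(locus_a) - self.position(locus_b))


@dataclass
class PhenotypeTable:
    """Long-format trait table: one row per (accession, environment).

    Trait columns are the four HVI fiber traits: FL (upper-half mean length,
    inches), FS (strength, g/tex), FM (micronaire index) and FU (length
    uniformity, %).  Missing values allowed.
    """

    table: pd.DataFrame
    units: dict[str, str] = field(
        default_factory=lambda: {"FL": "inch", "FS": "g/tex", "FM": "index", "FU": "%"}
    )
    #: True once traits are z-scored; disables instrument-scale range checks
    normalized: bool = False

    def __post_init__(self):
        required = ["accession", "environment", *TRAITS]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"phenotype table lacks columns {missing}")
        t = self.table
        if t.duplicated(["accession", "environment"]).any():
            key = t[t.duplicated(["accession", "environment"])].iloc[0]
            raise FormatError(
                f"duplicate (accession, environment) key: ({key['accession']}, {key['environment']})"
            )
        for trait in TRAITS:
            vals = t[trait].to_numpy(dtype=float)
            present = ~np.isnan(vals)
            if not np.isfinite(vals[present]).all():
                raise FormatError(f"non-finite values in trait {trait}")
        if not self.normalized:
            fu = t["FU"].to_numpy(dtype=float)
            ok = np.isnan(fu) | ((fu > 0) & (fu <= 100))
            if not ok.all():
                raise FormatError("FU outside (0, 100]")
            fm = t["FM"].to_numpy(dtype=float)
            if not (np.isnan(fm) | (fm > 0)).all():
                raise FormatError("FM must be positive")

    @property
    def environments(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.table["environment"]:
            seen.setdefault(e)
        return list(seen)

    def env(self, environment: str) -> pd.DataFrame:
        """Per-environment accession-indexed trait frame."""
        sub = self.table[self.table["environment"] == environment]
        if sub.empty:
            raise DataError(f"no rows for environment {environment!r}")
        return sub.set_index("accession")[list(TRAITS)].astype(float)


@dataclass
class GroupLabels:
    """Accession -> group (e.g. geographic origin) labels."""

    labels: dict[str, str]

    def __post_init__(self):
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def validate_against(self, panel: SSRPanel) -> None:
        unknown = [a for a in self.labels if a not in set(panel.accession_ids)]
        if unknown:
            raise DataError(f"labeled accessions absent from panel: {unknown[:5]}")

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc, lab in self.labels.items():
            out.setdefault(lab, []).append(acc)
        return out

    def vector(self, accession_ids: list[str]) -> np.ndarray:
        return np.array([self.labels.get(a, "unlabeled") for a in accession_ids], dtype=object)


# ---------------------------------------------------------------------------
# delimited-file plumbing
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    """Read a UTF-8 tab- or comma-delimited table, sniffing the delimiter."""
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    header = [t.strip() for t in head.rstrip("\n").split(sep)]
    dupes = {t for t in header if header.count(t) > 1}
    if dupes:
        # pandas would silently mangle repeated column names
        raise FormatError(f"{path}: duplicate column ids {sorted(dupes)[:5]}")
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def read_genotypes(path, dialect: str = "wide_binary", na_tokens=DEFAULT_NA_TOKENS) -> SSRPanel:
    """Read a wide binary genotype table into a validated :class:`SSRPanel`.

    First column holds accession ids, remaining columns allele-locus ids;
    cells must be 0, 1, or an NA token.
    """
    if dialect != "wide_binary":
        raise ParameterError(f"unknown genotype dialect {dialect!r}")
    df = _read_table(path)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: empty genotype table")
    acc = df.iloc[:, 0].tolist()
    loci = list(df.columns[1:])
    if len(set(acc)) != len(acc):
        raise FormatError(f"{path}: duplicate accession ids")
    if len(set(loci)) != len(loci):
        raise FormatError(f"{path}: duplicate locus ids")
    calls = np.empty((len(acc), len(loci)), dtype=float)
    na = set(na_tokens)
    for j, locus in enumerate(loci):
        col = df[locus].tolist()
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in na:
                calls[i, j] = np.nan
            elif cell == "0":
                calls[i, j] = 0.0
            elif cell == "1":
                calls[i, j] = 1.0
            else:
                raise ParseError(f"{path}: cell {cell!r} is not 0/1/NA", row=i, column=locus)
    return SSRPanel(acc, loci, calls)


def write_genotypes(panel: SSRPanel, path, na_token: str = "NA", sep: str = "\t") -> None:
    df = panel.to_dataframe()
    out = df.astype(object)
    out = out.where(~df.isna(), na_token)
    out = out.map(lambda v: v if isinstance(v, str) else str(int(v)))
    out.index.name = "accession"
    out.to_csv(path, sep=sep, encoding="utf-8")


def read_phenotypes(path, environments: list[str] | None = None, fs_unit_factor: float = 10.0) -> PhenotypeTable:
    """Read a long-format phenotype table.

    Expected columns: accession, environment, FL, FS, FM, FU.  If
    ``environments`` is given, any other environment label is an error.
    FS values that look like kN.m/kg (median > 100) are converted to g/tex
    by dividing by ``fs_unit_factor``.
    """
    df = _read_table(path)
    required = ["accession", "environment", *TRAITS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: phenotype table lacks columns {missing}")
    if df.empty:
        return PhenotypeTable(pd.DataFrame(columns=required))
    if environments is not None:
        bad = sorted(set(df["environment"]) - set(environments))
        if bad:
            raise FormatError(f"{path}: unknown environment labels {bad}")
    out = df[["accession", "environment"]].copy()
    for trait in TRAITS:
        vals = []
        for i, cell in enumerate(df[trait].tolist()):
            cell = cell.strip()
            if cell in DEFAULT_NA_TOKENS:
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(f"{path}: non-numeric trait cell {cell!r}", row=i, column=trait) from None
        out[trait] = vals
    fs = out["FS"].to_numpy(dtype=float)
    if np.isfinite(fs).any() and np.nanmedian(fs) > 100:
        # kN.m/kg scale; convert to g/tex
        out["FS"] = fs / fs_unit_factor
    return PhenotypeTable(out)


def write_phenotypes(pheno: PhenotypeTable, path, sep: str = "\t", na_token: str = "NA") -> None:
    pheno.table.to_csv(path, sep=sep, index=False, na_rep=na_token, encoding="utf-8")


def read_map(path) -> GeneticMap:
    """Read a locus/chromosome/position_cM table into a :class:`GeneticMap`."""
    df = _read_table(path)
    required = ["locus", "chromosome", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: map lacks columns {missing}")
    try:
        chrom = df["chromosome"].astype(int)
        pos = df["position_cM"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    table = pd.DataFrame({"chromosome": chrom.values, "position_cM": pos.values}, index=df["locus"].values)
    table.index.name = "locus"
    return GeneticMap(table)


def write_map(gmap: GeneticMap, path, sep: str = "\t") -> None:
    gmap.table.to_csv(path, sep=sep, encoding="utf-8")


def read_groups(path) -> GroupLabels:
    df = _read_table(path)
    if not {"accession", "group"} <= set(df.columns):
        raise FormatError(f"{path}: group table needs accession and group columns")
    if df["accession"].duplicated().any():
        raise FormatError(f"{path}: duplicate accession in group table")
    return GroupLabels(dict(zip(df["accession"], df["group"])))


def write_groups(groups: GroupLabels, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"accession": list(groups.labels), "group": list(groups.labels.values())}
    ).to_csv(path, sep=sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_newick(tree: skbio.TreeNode) -> str:
    """Serialize a tree to a Newick string parseable by standard tools."""
    s = str(tree)
    return s if s.endswith("\n") else s + "\n"


def read_newick(text: str) -> skbio.TreeNode:
    import io as _io

    return skbio.TreeNode.read(_io.StringIO(text), format="newick")
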