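"""Gene set library and gene statistic I/O.

Gene identifiers are treated as opaque strings throughout: any species- or
annotation-specific mapping (e.g. Ensembl to Entrez) is expected to happen
upstream, so a "gene" here is whatever key the ranking statistics are keyed by.

A :class:`GeneSetLibrary` keeps two membership views per set:

* the *full* view — every member listed in the library file, whether or not
  the gene was measured; this is the default basis for overlap/Jaccard
  similarity, on the grounds that curated membership is prior knowledge that
  does not depend on which genes a particular experiment detected;
* the *restricted* view — members intersected with the measured universe;
  this is what the enrichment test sees and what the ``NGenes`` column of
  result tables reports.

On a freshly loaded library the two views coincide; :func:`restrict_library`
is what makes them diverge.
"""

from __future__ import annotations

import io
import os
from collections.abc import Iterable, Iterator, Mapping
from typing import Optional

import pandas as pd

__all__ = [
    "GeneSetLibrary",
    "read_gmt",
    "write_gmt",
    "read_gene_stats",
    "restrict_library",
    "filter_by_prefix",
    "read_enrichment_table",
    "write_enrichment_table",
    "ENRICHMENT_COLUMNS",
]

#: canonical column order of enrichment result tables
ENRICHMENT_COLUMNS = ["name", "NGenes", "Direction", "PValue", "FDR"]


class GeneSetLibrary:
    """Ordered collection of named gene sets with dual membership views.

    Parameters
    ----------
    sets
        Mapping from set name to an iterable of member gene IDs. Iteration
        order of the mapping defines library order. Duplicate members within
        a set are dropped.
    full_sets
        Optional mapping holding the un-restricted membership for each set.
        Defaults to ``sets`` itself (fresh library). Used by
        :func:`restrict_library` to retain the original membership for
        similarity computation.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        full_sets: Optional[Mapping[str, Iterable[str]]] = None,
    ) -> None:
        self._sets: dict[str, frozenset[str]] = {}
        for name, members in sets.items():
            fs = frozenset(members)
            if name in self._sets:
                raise ValueError(f"duplicate set name: {name!r}")
            self._sets[name] = fs
        if full_sets is None:
            self._full = dict(self._sets)
        else:
            self._full = {n: frozenset(full_sets[n]) for n in self._sets}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, name: object) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return (
            list(self._sets) == list(other._sets)
            and self._sets == other._sets
            and self._full == other._full
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetLibrary({len(self)} sets)"

    # -- accessors ----------------------------------------------------------

    @property
    def names(self) -> list[str]:
        """Set names in library order."""
        return list(self._sets)

    @property
    def n_genes(self) -> dict[str, int]:
        """Distinct member count per set (restricted view)."""
        return {n: len(s) for n, s in self._sets.items()}

    def full_members(self, name: str) -> frozenset[str]:
        """Original (un-restricted) membership of ``name``."""
        return self._full[name]

    def members(self, name: str, view: str = "restricted") -> frozenset[str]:
        """Membership of ``name`` under the given view ('full'/'restricted')."""
        if view == "full":
            return self._full[name]
        if view == "restricted":
            return self._sets[name]
        raise ValueError(f"unknown membership view: {view!r}")

    def universe(self, view: str = "restricted") -> frozenset[str]:
        """Union of all member genes under the given view."""
        out: set[str] = set()
        for name in self._sets:
            out |= self.members(name, view)
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "GeneSetLibrary":
        """New library containing ``names`` in the given order."""
        names = list(names)
        missing = [n for n in names if n not in self._sets]
        if missing:
            raise KeyError(f"unknown set name(s): {missing}")
        return GeneSetLibrary(
            {n: self._sets[n] for n in names},
            full_sets={n: self._full[n] for n in names},
        )


def read_gmt(path: str | os.PathLike[str]) -> GeneSetLibrary:
    """Read a GMT (gene matrix transposed) gene set library.

    One set per line: ``name<TAB>description<TAB>gene1<TAB>gene2...``. The
    description column is ignored. Duplicate genes within a set are dropped;
    duplicate set names and lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetLibrary(sets)


def write_gmt(lib: GeneSetLibrary, path: str | os.PathLike[str]) -> None:
    """Write a library in GMT format (description column written as ``na``).

    Members are written sorted so that write/read round-trips compare equal.
    The full membership view is written.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for name in lib.names:
            genes = sorted(lib.full_members(name))
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gene_stats(path: str | os.PathLike[str] | io.TextIOBase) -> pd.DataFrame:
    """Read a two-column (gene_id, stat) table with header.

    Tab- and comma-separated files are both accepted. Returns a DataFrame
    with columns ``gene_id`` (str) and ``stat`` (float). Missing or
    non-numeric statistics and duplicate gene IDs are input errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene statistic table must have two columns (gene_id, stat)")
    df = df.iloc[:, :2].copy()
    df.columns = ["gene_id", "stat"]
    if df["gene_id"].isna().any():
        raise ValueError("gene statistic table contains missing gene IDs")
    df["gene_id"] = df["gene_id"].astype(str)
    dup = df["gene_id"][df["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene IDs in statistic table: {sorted(dup)[:10]}")
    stat = pd.to_numeric(df["stat"], errors="coerce")
    bad = df["gene_id"][stat.isna()].tolist()
    if bad:
        raise ValueError(f"missing or non-numeric statistics for genes: {bad[:10]}")
    df["stat"] = stat.astype(float)
    return df.reset_index(drop=True)


def restrict_library(
    lib: GeneSetLibrary,
    universe: Iterable[str],
    min_size: int = 1,
) -> GeneSetLibrary:
    """Intersect each set with the measured gene universe.

    Sets whose restricted size falls below ``min_size`` are dropped. The
    original full membership of surviving sets is retained for similarity
    computation. An empty ``universe`` is a sentinel for "no restriction":
    only the size filter applies.
    """
    uni = frozenset(universe)
    sets: dict[str, frozenset[str]] = {}
    full: dict[str, frozenset[str]] = {}
    for name in lib.names:
        members = lib.members(name, "restricted")
        if uni:
            members = members & uni
        if len(members) < min_size:
            continue
        sets[name] = members
        full[name] = lib.full_members(name)
    return GeneSetLibrary(sets, full_sets=full)


def filter_by_prefix(lib: GeneSetLibrary, prefixes: Iterable[str]) -> GeneSetLibrary:
    """Keep sets whose name starts with any of ``prefixes`` (e.g. KEGG_).

    Convenience for libraries that mix collections distinguished by the
    first underscore-delimited word of the set name.
    """
    pref = tuple(prefixes)
    keep = [n for n in lib.names if n.split("_")[0] in pref or n.startswith(pref)]
    return lib.subset(keep)


def read_enrichment_table(path: str | os.PathLike[str]) -> pd.DataFrame:
    """Read a precomputed enrichment table (TSV or CSV).

    Requires columns name, NGenes, Direction, FDR; PValue is optional and
    filled with NaN when absent. This is the entry point that lets the
    network stages run on results from any gene set testing method.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"name", "NGenes", "Direction", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enrichment table missing columns: {sorted(missing)}")
    if "PValue" not in df.columns:
        df["PValue"] = float("nan")
    bad_dir = set(df["Direction"].unique()) - {"Up", "Down", "Mixed"}
    if bad_dir:
        raise ValueError(f"unknown Direction values: {sorted(bad_dir)}")
    if df["name"].duplicated().any():
        raise ValueError("duplicate set names in enrichment table")
    return df[ENRICHMENT_COLUMNS].reset_index(drop=True)


def write_enrichment_table(df: pd.DataFrame, path: str | os.PathLike[str]) -> None:
    """Write an enrichment result table as TSV."""
    cols = [c for c in ENRICHMENT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
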