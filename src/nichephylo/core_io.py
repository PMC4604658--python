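"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline works on four kinds of objects:

* dereplicated amplicon sequences with per-sample read counts
  (:class:`SequenceRecord`, FASTA with a self-describing header),
* a soils-by-factors environmental table (:class:`EnvTable`, TSV),
* phylogenies with branch lengths and node supports (:class:`Phylogeny`,
  Newick with numeric internal labels), and
* soils-by-clusters relative-abundance matrices (:class:`AbundanceMatrix`,
  TSV of percentages).

All writers are exact inverses of the corresponding readers on valid data,
all outputs are UTF-8 with deterministic column order, and missing
environmental values are encoded as ``NA``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

MARKERS = ("16S", "amoA")

#: Factor vocabulary of the environmental table: soil physicochemistry,
#: nitrogen pools, climate means, and trace-metal concentrations.
CANONICAL_FACTORS = (
    "pH",
    "organic_matter_pct",     # % organic matter (loss on ignition)
    "carbon_pct",             # % carbon
    "bulk_density",           # g cm^-3
    "water_content",          # % H2O
    "vegetation",             # agricultural / grassland / forest / moorland
    "nitrogen_pct",           # % nitrogen
    "nitrogen_stock",         # t ha^-1
    "mineralisable_n_stock",  # kg N ha^-1
    "c_n_ratio",
    "phosphorus",             # Olsen PO4, mg kg^-1
    "total_mineralisable_n",  # mg N kg^-1 dry soil
    "nitrate_pct",            # % nitrate of the mineralisable N stock
    "air_temperature",        # mean annual, deg C
    "rain",                   # mean monthly, mm
    "sun",                    # mean hours per day
    # trace metals, mg kg^-1
    "Cd", "Cr", "Cu", "Ni", "Pb", "Zn", "Al", "Ti", "Mn", "As", "Se", "Mo",
    "Hg",
)

VEGETATION_LEVELS = ("agricultural", "grassland", "forest", "moorland")

#: Accepted aliases -> canonical factor name (case/space tolerant).
_FACTOR_ALIASES = {
    "ph": "pH",
    "% organic matter": "organic_matter_pct",
    "organic matter": "organic_matter_pct",
    "% carbon": "carbon_pct",
    "carbon": "carbon_pct",
    "bulk density": "bulk_density",
    "water content": "water_content",
    "% nitrogen": "nitrogen_pct",
    "nitrogen": "nitrogen_pct",
    "nitrogen stock": "nitrogen_stock",
    "mineralisable n stock": "mineralisable_n_stock",
    "c:n": "c_n_ratio",
    "c:n ratio": "c_n_ratio",
    "phosphorus": "phosphorus",
    "total mineralisable n": "total_mineralisable_n",
    "% nitrate": "nitrate_pct",
    "nitrate": "nitrate_pct",
    "air temperature": "air_temperature",
    "rain": "rain",
    "sun": "sun",
}

_PERCENT_FACTORS = {
    "organic_matter_pct", "carbon_pct", "water_content", "nitrogen_pct",
    "nitrate_pct",
}

_DNA = set("ACGT")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# SequenceRecord + FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One dereplicated amplicon read with its provenance.

    ``count`` is the number of reads the dereplicated sequence represents
    in sample ``sample_id``; ``marker`` is the gene it was amplified from.
    """

    id: str
    marker: str
    residues: str
    sample_id: str
    count: int

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _DNA
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-ACGT residues {sorted(bad)}")
        if self.count < 1:
            raise ValidationError(f"record {self.id!r}: count must be >= 1")


_HEADER_RE = re.compile(
    r"^(?P<id>[^|]+)\|sample=(?P<sid>[^|]+)\|count=(?P<n>\d+)"
    r"\|marker=(?P<m>[^|]+)$")


def _parse_header(header: str, lineno: int) -> tuple[str, str, int, str]:
    m = _HEADER_RE.match(header)
    if m is None:
        raise ParseError(
            f"line {lineno}: malformed FASTA header {header!r}; expected "
            ">{id}|sample={sid}|count={n}|marker={m}")
    return m["id"], m["sid"], int(m["n"]), m["m"]


def read_fasta(path) -> list[SequenceRecord]:
    """Read amplicon records from FASTA with the self-describing header
    dialect ``>{id}|sample={sid}|count={n}|marker={m}``.

    Order is preserved; ids must be unique within each marker.
    """
    from Bio import SeqIO

    records: list[SequenceRecord] = []
    # track header line numbers for error messages
    header_lines: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.setdefault(line[1:].strip(), i)
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        sid_, sample, count, marker = _parse_header(
            header, header_lines.get(header, 0))
        records.append(SequenceRecord(
            id=sid_, marker=marker, residues=str(entry.seq).upper(),
            sample_id=sample, count=count))
    _check_unique_ids(records)
    return records


def read_fasta_with_mapping(fasta_path, mapping_path) -> list[SequenceRecord]:
    """Read a plain-header FASTA plus a TSV mapping id -> sample, count, marker.

    Alternative loader for inputs whose headers are bare sequence ids;
    the mapping file must have columns ``id``, ``sample_id``, ``count``,
    ``marker``.
    """
    from Bio import SeqIO

    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    required = {"id", "sample_id", "count", "marker"}
    if not required <= set(mapping.columns):
        raise ParseError(
            f"mapping file missing columns {sorted(required - set(mapping.columns))}")
    mapping = mapping.set_index("id")
    records = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        key = entry.id
        if key not in mapping.index:
            raise ParseError(f"sequence {key!r} absent from mapping file")
        row = mapping.loc[key]
        records.append(SequenceRecord(
            id=key, marker=str(row["marker"]), residues=str(entry.seq).upper(),
            sample_id=str(row["sample_id"]), count=int(row["count"])))
    _check_unique_ids(records)
    return records


def _check_unique_ids(records) -> None:
    seen: dict[tuple[str, str], None] = {}
    for r in records:
        key = (r.marker, r.id)
        if key in seen:
            raise ValidationError(
                f"duplicate id {r.id!r} within marker {r.marker}")
        seen[key] = None


def write_fasta(records, path) -> None:
    """Write records in the same header dialect :func:`read_fasta` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.id}|sample={r.sample_id}|count={r.count}"
                     f"|marker={r.marker}\n{r.residues}\n")


# ---------------------------------------------------------------------------
# Phylogeny + Newick
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree with branch lengths (substitutions/site) and per-node
    supports in [0, 1], wrapping a :class:`dendropy.Tree`.

    Supports live on internal nodes as ``node.support`` (``None`` when the
    input carried no support, e.g. the root of a midpoint-rooted tree).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        seen = set()
        for leaf in self.tree.leaf_node_iter():
            label = _tip_label(leaf)
            if label is None:
                raise ValidationError("unlabelled tip")
            if label in seen:
                raise ValidationError(f"duplicate tip label {label!r}")
            seen.add(label)
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length {edge.length}")
        for nd in self.tree.preorder_node_iter():
            if not hasattr(nd, "support"):
                nd.support = None

    @property
    def tip_labels(self) -> list[str]:
        return [_tip_label(l) for l in self.tree.leaf_node_iter()]

    def copy(self) -> "Phylogeny":
        text = write_newick(self)
        return parse_newick(text)


def _tip_label(node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Numeric internal-node labels are interpreted as supports; values above 1
    are taken to be percentages and divided by 100. Bracketed comments are
    ignored (dendropy's default).
    """
    if text.count("(") != text.count(")"):
        raise ParseError("unbalanced parentheses in Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        nd.support = None
        if not nd.is_leaf() and nd.label is not None:
            try:
                val = float(nd.label)
            except ValueError:
                continue
            nd.support = val / 100.0 if val > 1.0 else val
            nd.label = None
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny) -> str:
    """Serialise with supports as internal-node labels (probability scale)."""
    tree = phylogeny.tree
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and getattr(nd, "support", None) is not None:
            nd.label = format(nd.support, ".10g")
    out = tree.as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g").strip() + "\n"
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            nd.label = None
    return out


def read_newick(path) -> Phylogeny:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(phylogeny: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(phylogeny))


# ---------------------------------------------------------------------------
# EnvTable + TSV
# ---------------------------------------------------------------------------

@dataclass
class EnvTable:
    """Soils-by-factors environmental table.

    ``data`` is indexed by soil id; numeric factors are floats with ``NaN``
    for missing values, ``vegetation`` (if present) is categorical over
    ``agricultural/grassland/forest/moorland``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate soil_id(s): {dups}")
        if "pH" in df.columns:
            ph = df["pH"].dropna()
            if ((ph < 0) | (ph > 14)).any():
                raise ValidationError("pH outside [0, 14]")
        for col in df.columns:
            if col in _PERCENT_FACTORS:
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValidationError(f"{col} outside [0, 100]")
            elif col != "vegetation" and pd.api.types.is_numeric_dtype(df[col]):
                if col in CANONICAL_FACTORS[16:] and (df[col].dropna() < 0).any():
                    raise ValidationError(f"negative concentration in {col}")
        if "vegetation" in df.columns:
            levels = set(df["vegetation"].dropna().astype(str))
            bad = levels - set(VEGETATION_LEVELS)
            if bad:
                raise ValidationError(f"unknown vegetation level(s) {sorted(bad)}")

    @property
    def soil_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def numeric_factors(self) -> list[str]:
        return [c for c in self.data.columns if c != "vegetation"]

    def factor(self, name: str) -> pd.Series:
        return self.data[name]


def canonicalise_factor(name: str) -> str:
    """Map a factor name (or accepted alias) to the canonical vocabulary."""
    if name in CANONICAL_FACTORS or name == "vegetation":
        return name
    key = name.strip().lower()
    if key in _FACTOR_ALIASES:
        return _FACTOR_ALIASES[key]
    return name  # unknown factors pass through untouched


def read_env_table(path) -> EnvTable:
    """Read a TSV environmental table (first column = soil id, ``NA`` =
    missing); factor names are canonicalised, numeric columns validated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0].lower() not in ("soil_id", "soil", "sample", "site"):
        # tolerate arbitrary first-column name; it is the id by contract
        pass
    df = df.set_index(df.columns[0])
    df.index.name = "soil_id"
    df.columns = [canonicalise_factor(c) for c in df.columns]
    out = {}
    for col in df.columns:
        raw = df[col]
        if col == "vegetation":
            out[col] = raw.replace("NA", np.nan)
            continue
        vals = []
        for soil, v in raw.items():
            if v == "NA" or v == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(v))
            except ValueError:
                raise ParseError(
                    f"non-numeric value {v!r} for factor {col!r}, soil "
                    f"{soil!r} (missing values must be 'NA')") from None
        out[col] = pd.Series(vals, index=df.index, dtype=float)
    return EnvTable(pd.DataFrame(out, index=df.index))


def write_env_table(env: EnvTable, path) -> None:
    df = env.data.copy()
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# AbundanceMatrix + TSV
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Soils x clusters table of relative read percentages.

    Rows of ``data`` sum to 100 over the retained clusters; soils whose read
    totals fell below the floor are listed in ``excluded`` and carry no row.
    """

    data: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValidationError("negative relative abundance")
        if len(self.data):
            sums = self.data.sum(axis=1).to_numpy()
            if not np.allclose(sums, 100.0, atol=1e-6):
                bad = self.data.index[~np.isclose(sums, 100.0, atol=1e-6)]
                raise ValidationError(
                    f"rows do not sum to 100: {list(bad)}")

    @property
    def soil_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.data.columns)


def read_abundance_matrix(path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    excluded = [str(i)[len("#excluded:"):] for i in df.index
                if str(i).startswith("#excluded:")]
    df = df[~df.index.astype(str).str.startswith("#excluded:")]
    return AbundanceMatrix(df.astype(float), excluded)


def write_abundance_matrix(mat: AbundanceMatrix, path) -> None:
    buf = io.StringIO()
    mat.data.to_csv(buf, sep="\t")
    for soil in mat.excluded:
        buf.write(f"#excluded:{soil}" + "\t" * len(mat.data.columns) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
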