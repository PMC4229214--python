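"""Readers and writers for every external file the pipeline touches.

Supported dialects: MAF-style somatic mutation TSV with configurable
column headers, a per-sample clinical TSV, gene-to-GO-term annotation
as either a two-column TSV or GAF 2.x, the GO ontology graph in OBO
1.2 (via ``obonet``), and the tab-separated screening summary table.
Everything is normalized into the small in-memory containers defined
here; gene symbols are upper-cased on input so MAF and annotation
files agree on HGNC symbols.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "MutationTable",
    "ClinicalTable",
    "GOAnnotation",
    "GODag",
    "read_maf",
    "read_clinical",
    "read_gene2go",
    "read_obo",
    "write_screening_table",
    "read_screening_table",
    "DEFAULT_MAF_COLUMNS",
    "DEFAULT_VITAL_STATUS_MAP",
]


class FormatError(ValueError):
    """An input file violates the expected format."""


#: canonical variant classes kept in a MutationTable
VARIANT_CLASSES = ("missense", "silent", "nonsense", "splice_site", "other")

_VARIANT_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "silent": "silent",
    "silence": "silent",
    "synonymous": "silent",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "splice_site": "splice_site",
    "splice_site_snp": "splice_site",
}

DEFAULT_MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "variant_class": "Variant_Classification",
    "validation_status": "Validation_Status",
}

_VALIDATED_STATUSES = {"valid", "validated", "yes", "true", "1"}

DEFAULT_VITAL_STATUS_MAP = {
    "dead": True,
    "deceased": True,
    "1": True,
    "true": True,
    "living": False,
    "alive": False,
    "0": False,
    "false": False,
}

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class MutationTable:
    """Long-format somatic mutation records.

    One row per mutation call: ``sample_id``, ``gene_symbol``,
    ``variant_class`` (one of :data:`VARIANT_CLASSES`), ``validated``.
    A gene may carry several mutations in one sample; each row counts
    separately when burdens are aggregated.
    """

    records: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "gene_symbol", "variant_class", "validated"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"MutationTable missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def filter_classes(self, keep: set[str]) -> "MutationTable":
        """Restrict to the given variant classes (e.g. drop silent)."""
        kept = self.records[self.records["variant_class"].isin(keep)]
        return MutationTable(kept.reset_index(drop=True))


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and covariates.

    Columns: ``sample_id`` (unique), ``os_months``, ``os_event``,
    ``pfs_months``/``pfs_event`` (may be NaN), ``age``.  ``n_skipped``
    counts input rows dropped for unparseable survival time or age.
    """

    rows: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self):
        required = {"sample_id", "os_months", "os_event", "age"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"ClinicalTable missing columns: {sorted(missing)}")
        dup = self.rows["sample_id"][self.rows["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample ids in clinical table: {sorted(set(dup))}")
        for col in ("pfs_months", "pfs_event"):
            if col not in self.rows.columns:
                self.rows[col] = np.nan

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    def subset(self, sample_ids) -> "ClinicalTable":
        """Rows for the given samples, in the given order."""
        idx = self.rows.set_index("sample_id")
        sub = idx.loc[list(sample_ids)].reset_index()
        return ClinicalTable(sub, n_skipped=0)

    def endpoint(self, which: str = "OS"):
        """(time, event) arrays for the OS or PFS endpoint.

        For PFS, samples with a missing endpoint are excluded; a boolean
        keep-mask aligned with the table rows is returned third.
        """
        which = which.upper()
        if which == "OS":
            keep = np.ones(len(self.rows), dtype=bool)
            return (
                self.rows["os_months"].to_numpy(float),
                self.rows["os_event"].to_numpy(bool),
                keep,
            )
        if which == "PFS":
            t = self.rows["pfs_months"].to_numpy(float)
            e = self.rows["pfs_event"].to_numpy()
            keep = np.isfinite(t) & pd.notna(e)
            return t[keep], e[keep].astype(bool), keep
        raise ValueError(f"unknown endpoint {which!r} (use 'OS' or 'PFS')")


@dataclass
class GOAnnotation:
    """Flat gene-to-term annotation: term id -> set of gene symbols."""

    term_to_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.term_to_genes)

    def genes(self, term: str) -> set[str]:
        return self.term_to_genes[term]

    def name(self, term: str) -> str:
        return self.term_names.get(term, "")


@dataclass
class GODag:
    """The GO term graph restricted to is_a and part_of edges.

    ``graph`` is a directed multigraph with edges from child to parent,
    keyed by relation.  Guaranteed acyclic on construction.
    """

    graph: nx.MultiDiGraph

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology graph contains a cycle through {cycle[0][0]!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def parents(self, term: str):
        """Iterate (parent, relation) pairs of a term."""
        for _, parent, rel in self.graph.out_edges(term, keys=True):
            yield parent, rel


def read_maf(path, validated_only: bool = False, column_map: dict | None = None) -> MutationTable:
    """Read a MAF-style tab-separated somatic mutation table.

    ``column_map`` overrides the default TCGA-style header names (keys
    ``gene``, ``sample``, ``variant_class``, ``validation_status``).
    With ``validated_only`` and a validation-status column present,
    only records whose status denotes experimental validation are
    kept; if the column is absent the flag is ignored with a warning.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("MAF file %s is empty", path)
        return MutationTable(
            pd.DataFrame(columns=["sample_id", "gene_symbol", "variant_class", "validated"])
        )
    for role in ("gene", "sample", "variant_class"):
        if cols[role] not in df.columns:
            raise FormatError(f"MAF file {path} lacks mandatory column {cols[role]!r}")

    n_raw = len(df)
    has_validation = cols["validation_status"] in df.columns
    if has_validation:
        validated = (
            df[cols["validation_status"]].fillna("").str.strip().str.lower().isin(_VALIDATED_STATUSES)
        )
    else:
        validated = pd.Series(False, index=df.index)
        if validated_only:
            logger.warning(
                "MAF file %s has no %r column; validated_only ignored",
                path,
                cols["validation_status"],
            )
    if validated_only and has_validation:
        df = df[validated]
        validated = validated[df.index]
    n_filtered = n_raw - len(df)
    logger.info("read %d MAF records from %s (%d filtered)", len(df), path, n_filtered)

    out = pd.DataFrame(
        {
            "sample_id": df[cols["sample"]].str.strip(),
            "gene_symbol": df[cols["gene"]].str.strip().str.upper(),
            "variant_class": df[cols["variant_class"]]
            .fillna("other")
            .str.strip()
            .str.lower()
            .map(lambda v: _VARIANT_MAP.get(v, "other")),
            "validated": validated.to_numpy(),
        }
    ).reset_index(drop=True)
    if (out["sample_id"] == "").any() or (out["gene_symbol"] == "").any():
        raise FormatError(f"MAF file {path} has empty gene or sample fields")
    return MutationTable(out)


def read_clinical(
    path,
    column_map: dict,
    vital_status_map: dict | None = None,
) -> ClinicalTable:
    """Read a tab-separated clinical table.

    ``column_map`` maps semantic roles to header names; required roles
    are ``sample``, ``os_months``, ``os_event`` and ``age``; optional
    roles ``pfs_months`` and ``pfs_event``.  Vital-status strings are
    converted to booleans through ``vital_status_map`` (case
    insensitive; default :data:`DEFAULT_VITAL_STATUS_MAP`).  Rows with
    unparseable OS time or age are dropped and counted in
    ``n_skipped``.
    """
    vmap = {k.lower(): v for k, v in (vital_status_map or DEFAULT_VITAL_STATUS_MAP).items()}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for role in ("sample", "os_months", "os_event", "age"):
        if role not in column_map:
            raise FormatError(f"column_map lacks required role {role!r}")
        if column_map[role] not in df.columns:
            raise FormatError(f"clinical file {path} lacks column {column_map[role]!r}")

    def to_event(series):
        return series.fillna("").str.strip().str.lower().map(vmap)

    os_months = pd.to_numeric(df[column_map["os_months"]], errors="coerce")
    age = pd.to_numeric(df[column_map["age"]], errors="coerce")
    os_event = to_event(df[column_map["os_event"]])
    ok = os_months.notna() & (os_months >= 0) & age.notna() & (age > 0) & os_event.notna()
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("clinical file %s: skipped %d unparseable rows", path, n_skipped)

    out = pd.DataFrame(
        {
            "sample_id": df[column_map["sample"]].str.strip(),
            "os_months": os_months,
            "os_event": os_event,
            "age": age,
        }
    )
    if "pfs_months" in column_map and column_map["pfs_months"] in df.columns:
        out["pfs_months"] = pd.to_numeric(df[column_map["pfs_months"]], errors="coerce")
    if "pfs_event" in column_map and column_map["pfs_event"] in df.columns:
        out["pfs_event"] = to_event(df[column_map["pfs_event"]])
    out = out[ok].reset_index(drop=True)
    out["os_event"] = out["os_event"].astype(bool)
    return ClinicalTable(out, n_skipped=n_skipped)


def read_gene2go(path, format: str = "two_column_tsv") -> GOAnnotation:
    """Read gene-to-GO-term annotation.

    ``two_column_tsv`` expects (gene, term) pairs, one per line; GAF
    2.x files use the standard column positions (symbol in column 3,
    qualifier in 4, GO id in 5) and rows with a NOT qualifier are
    skipped.  Duplicate (gene, term) pairs collapse; malformed GO ids
    raise with the offending line number.
    """
    term_to_genes: dict[str, set[str]] = {}

    def add(gene: str, term: str, lineno: int):
        if not GO_ID_RE.match(term):
            raise FormatError(f"{path}:{lineno}: malformed GO id {term!r}")
        term_to_genes.setdefault(term, set()).add(gene.upper())

    with open(path) as fh:
        if format == "two_column_tsv":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("!", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
                add(parts[0].strip(), parts[1].strip(), lineno)
        elif format == "gaf":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    raise FormatError(f"{path}:{lineno}: GAF line has fewer than 5 columns")
                qualifier = parts[3]
                if "NOT" in qualifier.split("|"):
                    continue
                add(parts[2].strip(), parts[4].strip(), lineno)
        else:
            raise ValueError(f"unknown annotation format {format!r}")
    return GOAnnotation(term_to_genes=term_to_genes)


def read_obo(path) -> GODag:
    """Read an OBO 1.2 ontology into a :class:`GODag`.

    Only ``is_a`` and ``part_of`` edges are retained (others dropped
    with a warning); obsolete terms are excluded; a cycle raises a
    :class:`FormatError` naming one participating term.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.MultiDiGraph()
    graph.add_nodes_from((n, d) for n, d in raw.nodes(data=True))
    dropped = 0
    for child, parent, rel in raw.edges(keys=True):
        if rel in ("is_a", "part_of"):
            graph.add_edge(child, parent, key=rel)
        else:
            dropped += 1
    if dropped:
        logger.warning("read_obo: dropped %d edges with unsupported relations", dropped)
    return GODag(graph=graph)


_SCREEN_COLUMNS = ["term_id", "beta", "cox_p", "logrank_p", "cp", "n1", "n2", "name"]


def _fmt_p(p: float) -> str:
    return f"{p:.1E}"  # two significant digits, scientific notation


def write_screening_table(results, path) -> None:
    """Write screening associations as a TSV.

    Column order follows the published summary layout: term id, Cox
    coefficient, Cox p, log-rank p, composite p, member-gene count N1,
    mutated-member-gene count N2, term name.  P-values are printed with
    two significant digits in scientific notation.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_SCREEN_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.term_id,
                        f"{r.beta:.2f}",
                        _fmt_p(r.p_cox),
                        _fmt_p(r.p_rank),
                        _fmt_p(r.cp),
                        str(r.n1),
                        str(r.n2),
                        r.term_name,
                    ]
                )
                + "\n"
            )


def read_screening_table(path) -> pd.DataFrame:
    """Read back a screening TSV written by :func:`write_screening_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"term_id": str, "name": str})
    missing = set(_SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"screening table {path} lacks columns {sorted(missing)}")
    return df


def intersect_samples(mutations: MutationTable, clinical: ClinicalTable):
    """Samples present in both tables, with dropped counts logged.

    Returns (sample_ids, clinical restricted to them, in mutation-table
    independent sorted order).
    """
    mut_samples = set(mutations.records["sample_id"])
    clin_samples = set(clinical.sample_ids)
    common = sorted(mut_samples & clin_samples)
    logger.info(
        "sample intersection: %d common, %d mutation-only, %d clinical-only",
        len(common),
        len(mut_samples - clin_samples),
        len(clin_samples - mut_samples),
    )
    return common, clinical.subset(common)
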