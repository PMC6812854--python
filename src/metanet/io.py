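"""Integrated data model and TSV round-tripping.

Four flat tables describe the system:

``domains.tsv``
    one row per (enzyme, SCOP fold-family) domain assignment with the
    fold family's *nd* ancestry value in [0, 1];
``membership.tsv``
    one row per (enzyme, subnetwork) pathway membership — an enzyme in
    several subnetworks is the sharing signal the analysis lives on;
``hierarchy.tsv``
    one row per subnetwork (KEGG map) with its mesonetwork code;
``taxa.tsv`` / ``functions.tsv`` / ``catalysis.tsv`` (optional)
    superkingdom occurrence, SCOP-superfamily functional categories and
    catalytic-residue annotations.

All tables are UTF-8 TSV with one header row.  Reading deduplicates,
cross-references membership against the hierarchy and validates value
ranges; writing sorts rows canonically so outputs are diffable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

MESO_CODES = ("AAC", "SEC", "CAR", "NRG", "GLY", "LIP", "COF", "POL", "NUC", "AA2", "XEN")

SUPERKINGDOMS = ("A", "B", "E", "V")

GENERAL_CATEGORIES = (
    "Metabolism",
    "Information",
    "Processes_IC",
    "Processes_EC",
    "Regulation",
    "General",
    "Other",
)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_CCS_RE = re.compile(r"^[a-z]\.\d+\.\d+\.\d+$")

_CORE_SCHEMAS: dict[str, list[str]] = {
    "domains": ["ec", "scop_ccs", "nd"],
    "membership": ["ec", "map_id"],
    "hierarchy": ["map_id", "map_name", "meso_code"],
}
_ANNOT_SCHEMAS: dict[str, list[str]] = {
    "taxa": ["ec", "species", "superkingdom"],
    "functions": ["fsf_id", "general", "detailed"],
    "catalysis": ["ec", "residue", "role_group"],
}


class DatasetError(ValueError):
    """Schema or validation failure in an input table."""


@dataclass
class AnnotationTables:
    """Optional annotation layer: taxonomy, function and catalysis."""

    taxa: pd.DataFrame | None = None        # columns ec, species, superkingdom
    functions: pd.DataFrame | None = None   # columns fsf_id, general, detailed
    catalysis: pd.DataFrame | None = None   # columns ec, residue, role_group

    def taxa_sets(self) -> dict[str, frozenset[str]]:
        """Collapse the taxa table to ec -> set of superkingdom letters."""
        if self.taxa is None or self.taxa.empty:
            return {}
        grouped = self.taxa.groupby("ec")["superkingdom"].agg(lambda s: frozenset(s))
        return dict(grouped)


@dataclass
class Dataset:
    """In-memory integrated dataset consumed by every analysis stage."""

    domains: pd.DataFrame      # columns ec, scop_ccs, nd
    membership: pd.DataFrame   # columns ec, map_id
    hierarchy: pd.DataFrame    # columns map_id, map_name, meso_code
    annotations: AnnotationTables | None = None
    unresolved_map_ids: list[str] = field(default_factory=list)

    @property
    def enzymes(self) -> list[str]:
        """Enzymes known to the dataset (from domains or membership)."""
        seen = set(self.domains["ec"]) | set(self.membership["ec"])
        return sorted(seen)

    def meso_of(self) -> Mapping[str, str]:
        return dict(zip(self.hierarchy["map_id"], self.hierarchy["meso_code"]))

    def domain_ages(self) -> dict[str, list[float]]:
        """ec -> multiset (list) of domain nd values, duplicates kept."""
        out: dict[str, list[float]] = {}
        for ec, grp in self.domains.groupby("ec"):
            out[str(ec)] = sorted(grp["nd"].tolist())
        return out


@dataclass
class ValidationReport:
    n_enzymes: int
    n_subnetworks: int
    n_mesonetworks: int
    n_domain_assignments: int
    n_membership_links: int
    painting_coverage: float
    orphan_map_ids: list[str]
    unpainted_enzymes: list[str]

    def as_dict(self) -> dict:
        return {
            "n_enzymes": self.n_enzymes,
            "n_subnetworks": self.n_subnetworks,
            "n_mesonetworks": self.n_mesonetworks,
            "n_domain_assignments": self.n_domain_assignments,
            "n_membership_links": self.n_membership_links,
            "painting_coverage": self.painting_coverage,
            "orphan_map_ids": list(self.orphan_map_ids),
            "unpainted_enzymes": list(self.unpainted_enzymes),
        }


def _read_table(path: Path, name: str, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DatasetError(f"{name} table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in columns:
        if col not in df.columns:
            raise DatasetError(f"{path}: missing required column '{col}'")
    return df[columns]


def _validate_domains(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    df = df.copy()
    df["nd"] = pd.to_numeric(df["nd"], errors="coerce")
    bad_nd = df.index[df["nd"].isna() | (df["nd"] < 0) | (df["nd"] > 1)]
    if len(bad_nd):
        row = int(bad_nd[0])
        raise DatasetError(
            f"{origin}: nd outside [0,1] (or non-numeric) at row {row + 2} "
            f"(ec={df.loc[row, 'ec']}, scop_ccs={df.loc[row, 'scop_ccs']})"
        )
    bad_ccs = df.index[~df["scop_ccs"].astype(str).str.match(_CCS_RE)]
    if len(bad_ccs):
        row = int(bad_ccs[0])
        raise DatasetError(
            f"{origin}: malformed SCOP ccs '{df.loc[row, 'scop_ccs']}' at row {row + 2}"
        )
    # exact duplicate rows collapse silently; conflicting nd for the same
    # fold family in the same enzyme is an error (one age per fold family)
    df = df.drop_duplicates()
    conflicts = df.groupby(["ec", "scop_ccs"])["nd"].nunique()
    conflicts = conflicts[conflicts > 1]
    if len(conflicts):
        ec, ccs = conflicts.index[0]
        raise DatasetError(f"{origin}: conflicting nd values for ({ec}, {ccs})")
    return df.reset_index(drop=True)


def read_dataset(
    dir_or_paths: str | Path | Mapping[str, str | Path],
) -> Dataset:
    """Read the core tables (plus any annotation tables present).

    Accepts either a directory containing the canonically named files or
    an explicit mapping ``{"domains": path, "membership": path, ...}``.
    """
    if isinstance(dir_or_paths, (str, Path)):
        base = Path(dir_or_paths)
        paths: dict[str, Path] = {
            name: base / f"{name}.tsv" for name in (*_CORE_SCHEMAS, *_ANNOT_SCHEMAS)
        }
    else:
        paths = {k: Path(v) for k, v in dir_or_paths.items()}

    domains = _validate_domains(
        _read_table(paths["domains"], "domains", _CORE_SCHEMAS["domains"]),
        str(paths["domains"]),
    )
    membership = _read_table(
        paths["membership"], "membership", _CORE_SCHEMAS["membership"]
    ).drop_duplicates().reset_index(drop=True)
    hierarchy = _read_table(
        paths["hierarchy"], "hierarchy", _CORE_SCHEMAS["hierarchy"]
    ).drop_duplicates().reset_index(drop=True)

    dup_map = hierarchy["map_id"][hierarchy["map_id"].duplicated()]
    if len(dup_map):
        raise DatasetError(
            f"hierarchy: map_id '{dup_map.iloc[0]}' assigned to more than one mesonetwork"
        )
    bad_meso = hierarchy[~hierarchy["meso_code"].isin(MESO_CODES)]
    if len(bad_meso):
        raise DatasetError(
            f"hierarchy: unknown meso_code '{bad_meso['meso_code'].iloc[0]}' "
            f"(expected one of {', '.join(MESO_CODES)})"
        )

    known_maps = set(hierarchy["map_id"])
    unresolved = sorted(set(membership["map_id"]) - known_maps)

    annotations = None
    annot_frames: dict[str, pd.DataFrame | None] = {}
    for name, cols in _ANNOT_SCHEMAS.items():
        p = paths.get(name)
        if p is not None and Path(p).exists():
            annot_frames[name] = _read_table(Path(p), name, cols).drop_duplicates().reset_index(drop=True)
        else:
            annot_frames[name] = None
    if any(v is not None for v in annot_frames.values()):
        annotations = AnnotationTables(
            taxa=annot_frames["taxa"],
            functions=annot_frames["functions"],
            catalysis=annot_frames["catalysis"],
        )

    return Dataset(
        domains=domains,
        membership=membership,
        hierarchy=hierarchy,
        annotations=annotations,
        unresolved_map_ids=unresolved,
    )


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report-only summary: counts, orphans and painting coverage.

    Painting coverage is the fraction of enzymes (anything appearing in
    domains or membership) that carry at least one domain age — the
    analog of the database's per-map painting efficiency.
    """
    enzymes = ds.enzymes
    painted = set(ds.domains["ec"])
    unpainted = sorted(set(enzymes) - painted)
    coverage = (len(enzymes) - len(unpainted)) / len(enzymes) if enzymes else 0.0
    return ValidationReport(
        n_enzymes=len(enzymes),
        n_subnetworks=ds.hierarchy["map_id"].nunique(),
        n_mesonetworks=ds.hierarchy["meso_code"].nunique(),
        n_domain_assignments=len(ds.domains),
        n_membership_links=len(ds.membership),
        painting_coverage=coverage,
        orphan_map_ids=list(ds.unresolved_map_ids),
        unpainted_enzymes=unpainted,
    )


def _canonical(ds: Dataset) -> Dataset:
    domains = ds.domains.sort_values(["ec", "scop_ccs"], kind="mergesort").reset_index(drop=True)
    membership = ds.membership.sort_values(["ec", "map_id"], kind="mergesort").reset_index(drop=True)
    hierarchy = ds.hierarchy.sort_values(["map_id"], kind="mergesort").reset_index(drop=True)
    return Dataset(domains, membership, hierarchy, ds.annotations, ds.unresolved_map_ids)


def write_dataset(ds: Dataset, out_dir: str | Path) -> list[Path]:
    """Write the dataset as canonical TSV files; returns paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _canonical(ds)
    written: list[Path] = []

    def _dump(df: pd.DataFrame, name: str) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)

    dom = ds.domains.copy()
    # repr-round floats so the round trip is byte-stable
    dom["nd"] = dom["nd"].map(lambda v: format(float(v), "g"))
    _dump(dom, "domains")
    _dump(ds.membership, "membership")
    _dump(ds.hierarchy, "hierarchy")
    if ds.annotations is not None:
        ann = ds.annotations
        if ann.taxa is not None:
            _dump(ann.taxa.sort_values(["ec", "species"], kind="mergesort"), "taxa")
        if ann.functions is not None:
            _dump(ann.functions.sort_values(["fsf_id"], kind="mergesort"), "functions")
        if ann.catalysis is not None:
            _dump(
                ann.catalysis.sort_values(["ec", "residue"], kind="mergesort"),
                "catalysis",
            )
    return written
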