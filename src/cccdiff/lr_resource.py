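"""Ligand-receptor interaction resources.

A communication database is a flat table of ligand-receptor interactions.
Each side of an interaction may be a heteromeric complex (an ordered list of
gene symbols); interactions carry optional cofactor annotations (soluble
agonists/antagonists acting on the sender side, membrane-bound
co-stimulatory/co-inhibitory receptors acting on the receiver side) and
belong to exactly one signaling-pathway family, so pathways partition the
interaction set.

The on-disk format is a TSV with columns

    id, ligand_name, ligand_subunits, receptor_name, receptor_subunits,
    pathway, agonists, antagonists, co_stimulatory, co_inhibitory, category

where multi-gene fields are ``_``-delimited (the convention of common L-R
resources such as CellChatDB, whose complexes are written ``NRXN1_NLGN2``).
Exports from CellChatDB or CellPhoneDB can be converted to this schema by
flattening their complex and cofactor tables; no third-party database
content ships with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Delimiter joining subunits / list entries in the tabular format.
SUBUNIT_DELIMITER = "_"

CATEGORIES = ("secreted", "ecm_receptor", "cell_contact")

MANDATORY_COLUMNS = (
    "id",
    "ligand_name",
    "ligand_subunits",
    "receptor_name",
    "receptor_subunits",
    "pathway",
)

OPTIONAL_COLUMNS = (
    "agonists",
    "antagonists",
    "co_stimulatory",
    "co_inhibitory",
    "category",
)


class SchemaError(ValueError):
    """The tabular file does not follow the documented column schema."""


class ValidationError(ValueError):
    """The database content violates an invariant."""


@dataclass(frozen=True)
class GeneComplex:
    """A protein complex: one or more gene symbols acting as a unit."""

    name: str
    subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.subunits) == 0:
            raise ValidationError(f"complex {self.name!r} has no subunits")
        if len(set(self.subunits)) != len(self.subunits):
            raise ValidationError(f"complex {self.name!r} has duplicate subunits")

    @classmethod
    def from_string(
        cls, text: str, name: str | None = None, delimiter: str = SUBUNIT_DELIMITER
    ) -> "GeneComplex":
        subunits = tuple(s for s in text.split(delimiter) if s)
        return cls(name=name if name is not None else text, subunits=subunits)


@dataclass(frozen=True)
class LRInteraction:
    """One ligand(complex)-receptor(complex) pair with cofactor annotation."""

    id: str
    ligand: GeneComplex
    receptor: GeneComplex
    pathway: str
    agonists: tuple[str, ...] = ()
    antagonists: tuple[str, ...] = ()
    co_stimulatory: tuple[str, ...] = ()
    co_inhibitory: tuple[str, ...] = ()
    category: str = "secreted"

    def __post_init__(self) -> None:
        if not self.pathway:
            raise ValidationError(f"interaction {self.id!r} has empty pathway label")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"interaction {self.id!r}: unknown category {self.category!r}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        """All genes touched by this interaction (subunits then cofactors)."""
        return (
            self.ligand.subunits
            + self.receptor.subunits
            + self.agonists
            + self.antagonists
            + self.co_stimulatory
            + self.co_inhibitory
        )


@dataclass
class LRDatabase:
    """A validated collection of L-R interactions partitioned into pathways."""

    interactions: list[LRInteraction]
    pathways: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.interactions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate interaction ids: {dup}")
        names: dict[str, tuple[str, ...]] = {}
        for it in self.interactions:
            for cplx in (it.ligand, it.receptor):
                seen = names.get(cplx.name)
                if seen is not None and seen != cplx.subunits:
                    raise ValidationError(
                        f"complex name {cplx.name!r} maps to different subunit lists"
                    )
                names[cplx.name] = cplx.subunits
        self.pathways = {}
        for it in self.interactions:
            self.pathways.setdefault(it.pathway, []).append(it.id)

    def __len__(self) -> int:
        return len(self.interactions)

    def __getitem__(self, interaction_id: str) -> LRInteraction:
        for it in self.interactions:
            if it.id == interaction_id:
                return it
        raise KeyError(interaction_id)

    @property
    def genes(self) -> list[str]:
        """Sorted union of all genes referenced by the database."""
        out: set[str] = set()
        for it in self.interactions:
            out.update(it.genes)
        return sorted(out)


def _split_list(value: object, delimiter: str) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(s for s in text.split(delimiter) if s)


def read_lr_database(path, delimiter: str = SUBUNIT_DELIMITER) -> LRDatabase:
    """Read an interaction database from its tabular (TSV) form.

    Unknown columns are ignored with a logged warning; a missing mandatory
    column raises :class:`SchemaError`, duplicate ids or empty complexes
    raise :class:`ValidationError`.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    unknown = [
        c for c in table.columns if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    ]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", unknown)

    interactions = []
    for row in table.itertuples(index=False):
        rec = row._asdict()
        lig = GeneComplex.from_string(
            str(rec["ligand_subunits"]), name=str(rec["ligand_name"]), delimiter=delimiter
        )
        rec_cplx = GeneComplex.from_string(
            str(rec["receptor_subunits"]),
            name=str(rec["receptor_name"]),
            delimiter=delimiter,
        )
        interactions.append(
            LRInteraction(
                id=str(rec["id"]),
                ligand=lig,
                receptor=rec_cplx,
                pathway=str(rec["pathway"]),
                agonists=_split_list(rec.get("agonists"), delimiter),
                antagonists=_split_list(rec.get("antagonists"), delimiter),
                co_stimulatory=_split_list(rec.get("co_stimulatory"), delimiter),
                co_inhibitory=_split_list(rec.get("co_inhibitory"), delimiter),
                category=str(rec.get("category") or "secreted"),
            )
        )
    return LRDatabase(interactions=interactions)


def write_lr_database(db: LRDatabase, path, delimiter: str = SUBUNIT_DELIMITER) -> None:
    """Write the canonical tabular form (fixed column order, ``_`` lists)."""
    rows = []
    for it in db.interactions:
        rows.append(
            {
                "id": it.id,
                "ligand_name": it.ligand.name,
                "ligand_subunits": delimiter.join(it.ligand.subunits),
                "receptor_name": it.receptor.name,
                "receptor_subunits": delimiter.join(it.receptor.subunits),
                "pathway": it.pathway,
                "agonists": delimiter.join(it.agonists),
                "antagonists": delimiter.join(it.antagonists),
                "co_stimulatory": delimiter.join(it.co_stimulatory),
                "co_inhibitory": delimiter.join(it.co_inhibitory),
                "category": it.category,
            }
        )
    cols = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def pathway_gene_set(db: LRDatabase, pathway: str) -> list[str]:
    """Deduplicated union of subunit and cofactor genes of a pathway.

    Raises ``KeyError`` for an unknown pathway label.
    """
    if pathway not in db.pathways:
        raise KeyError(f"unknown pathway: {pathway!r}")
    wanted = set(db.pathways[pathway])
    genes: set[str] = set()
    for it in db.interactions:
        if it.id in wanted:
            genes.update(it.genes)
    return sorted(genes)
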