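"""Typed binding-affinity dataset for the pyrimidine-5-carbonitrile library.

The library consists of 2-amino-4,6-disubstituted-pyrimidine-5-carbonitriles
profiled by radioligand displacement at the four human adenosine receptor
subtypes (A1, A2A, A2B, A3).  Each table cell is either a fitted
equilibrium inhibition constant ``Ki ± SEM`` in nM, or — when the compound
did not fully displace the radioligand — the percent displacement of
specific binding at a single 1 μM test concentration.

Structures are not stored explicitly in the source tables; they are
assembled here from the scaffold substituent codes (R2 amine, R4 and R6
aryl/alkyl groups) and canonicalized with RDKit.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem

__all__ = [
    "Receptor",
    "AffinityKind",
    "AffinityEntry",
    "CompoundRecord",
    "CompoundTable",
    "ParseError",
    "ValidationError",
    "parse_affinity_cell",
    "assemble_smiles",
    "load_compound_table",
    "packaged_dataset_path",
    "export_structures",
    "R4_R6_VOCABULARY",
    "R2_VOCABULARY",
]


class ParseError(ValueError):
    """A table cell (or row) could not be interpreted."""


class ValidationError(ValueError):
    """Parsed data violates a dataset invariant."""


class Receptor(str, enum.Enum):
    A1 = "A1"
    A2A = "A2A"
    A2B = "A2B"
    A3 = "A3"


class AffinityKind(str, enum.Enum):
    QUANTITATIVE = "quantitative"
    PERCENT = "percent"


@dataclass(frozen=True)
class AffinityEntry:
    """One binding-table cell for one receptor.

    Exactly one of ``ki_nM`` / ``percent_at_1uM`` is populated, matching
    ``kind``.
    """

    receptor: Receptor
    kind: AffinityKind
    ki_nM: float | None = None
    sem_nM: float | None = None
    percent_at_1uM: float | None = None

    def __post_init__(self) -> None:
        if self.kind is AffinityKind.QUANTITATIVE:
            if self.ki_nM is None or self.percent_at_1uM is not None:
                raise ValidationError(
                    f"quantitative entry must set ki_nM only: {self!r}"
                )
            if self.ki_nM <= 0:
                raise ValidationError(f"ki_nM must be positive: {self.ki_nM}")
            if self.sem_nM is not None and self.sem_nM < 0:
                raise ValidationError(f"sem_nM must be >= 0: {self.sem_nM}")
        else:
            if self.percent_at_1uM is None or self.ki_nM is not None:
                raise ValidationError(
                    f"percent entry must set percent_at_1uM only: {self!r}"
                )
            if not 0.0 <= self.percent_at_1uM <= 100.0:
                raise ValidationError(
                    f"percent displacement out of [0, 100]: {self.percent_at_1uM}"
                )

    @property
    def is_quantitative(self) -> bool:
        return self.kind is AffinityKind.QUANTITATIVE


#: R2 exocyclic amine codes -> SMILES fragment bonded to the C2 ring carbon.
R2_VOCABULARY: Mapping[str, str] = {
    "NH2": "N",
    "NHMe": "NC",
    "NHEt": "NCC",
    "NHPh": "Nc2ccccc2",
    "NMe2": "N(C)C",
}

#: R4/R6 substituent codes -> SMILES fragment bonded to the ring carbon.
#: "3,4-OCH2O-Ph" is the benzo[d][1,3]dioxol-5-yl (piperonyl) group.
R4_R6_VOCABULARY: Mapping[str, str] = {
    "Ph": "c2ccccc2",
    "2-F-Ph": "c2ccccc2F",
    "2-Cl-Ph": "c2ccccc2Cl",
    "2-MeO-Ph": "c2ccccc2OC",
    "3-F-Ph": "c2cccc(F)c2",
    "3-Cl-Ph": "c2cccc(Cl)c2",
    "3-MeO-Ph": "c2cccc(OC)c2",
    "3-OH-Ph": "c2cccc(O)c2",
    "3-CN-Ph": "c2cccc(C#N)c2",
    "4-F-Ph": "c2ccc(F)cc2",
    "4-Br-Ph": "c2ccc(Br)cc2",
    "4-MeO-Ph": "c2ccc(OC)cc2",
    "4-OH-Ph": "c2ccc(O)cc2",
    "4-Me-Ph": "c2ccc(C)cc2",
    "2,4-F-Ph": "c2ccc(F)cc2F",
    "2,4-Cl-Ph": "c2ccc(Cl)cc2Cl",
    "2,4-MeO-Ph": "c2ccc(OC)cc2OC",
    "3,5-F-Ph": "c2cc(F)cc(F)c2",
    "3,5-Cl-Ph": "c2cc(Cl)cc(Cl)c2",
    "3,5-MeO-Ph": "c2cc(OC)cc(OC)c2",
    "3,4-OCH2O-Ph": "c2ccc3c(c2)OCO3",
    "3,4,5-MeO-Ph": "c2cc(OC)c(OC)c(OC)c2",
    "2,4,6-F-Ph": "c2c(F)cc(F)cc2F",
    "2-furyl": "c2ccco2",
    "2-thienyl": "c2cccs2",
    "3-furyl": "c2ccoc2",
    "3-thienyl": "c2ccsc2",
    "4-pyridyl": "c2ccncc2",
    "3-pyridyl": "c2cccnc2",
    "cPent": "C2CCCC2",
    "cHex": "C2CCCCC2",
    "2-naphthyl": "c2ccc3ccccc3c2",
    "4-Ph-Ph": "c2ccc(-c3ccccc3)cc2",
}

_SERIES_BY_R2 = {
    "NH2": "I",
    "NHMe": "II",
    "NHEt": "II",
    "NHPh": "II",
    "NMe2": "III",
}


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    series: str
    r2: str
    r4: str
    r6: str
    smiles: str
    affinities: Mapping[Receptor, AffinityEntry]
    alt_label: str | None = None

    def __post_init__(self) -> None:
        if set(self.affinities) != set(Receptor):
            raise ValidationError(
                f"{self.compound_id}: all four receptors required, got "
                f"{sorted(r.value for r in self.affinities)}"
            )
        expected = _SERIES_BY_R2.get(self.r2)
        if expected is None:
            raise ValidationError(f"{self.compound_id}: unknown R2 code {self.r2!r}")
        if self.series != expected:
            raise ValidationError(
                f"{self.compound_id}: series {self.series} inconsistent with "
                f"R2={self.r2} (expected series {expected})"
            )

    def affinity(self, receptor: Receptor | str) -> AffinityEntry:
        return self.affinities[Receptor(receptor)]


@dataclass
class CompoundTable:
    """Ordered library records plus reference ligands (kept separate)."""

    records: list[CompoundRecord]
    references: list["ReferenceRecord"] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate compound_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def series_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.series] = counts.get(rec.series, 0) + 1
        return counts

    def subset(self, compound_ids: Iterable[str]) -> "CompoundTable":
        return CompoundTable(
            records=[self.get(i) for i in compound_ids], references=[]
        )


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference ligand (e.g. XAC, DPCPX, ZM241385): affinity row only."""

    compound_id: str
    smiles: str | None
    affinities: Mapping[Receptor, AffinityEntry]


# "12.3 ± 4.5" (also the "+/-" ASCII alias) or "33%"
_QUANT_RE = re.compile(
    r"^(?P<ki>\d+(?:\.\d+)?)\s*(?:±|\+/-)\s*(?:(?P<sem>\d+(?:\.\d+)?))$"
)
_PERCENT_RE = re.compile(r"^(?P<pct>-?\d+(?:\.\d+)?)\s*%$")


def parse_affinity_cell(text: str, receptor: Receptor | str) -> AffinityEntry:
    """Parse one raw binding-table cell.

    Accepts ``"<Ki> ± <SEM>"`` (nM) or ``"<percent>%"`` (displacement at
    1 μM).  Anything else — including "n.d." placeholders — raises
    :class:`ParseError` naming the offending text.
    """
    receptor = Receptor(receptor)
    norm = " ".join(str(text).split())
    m = _QUANT_RE.match(norm)
    if m:
        return AffinityEntry(
            receptor=receptor,
            kind=AffinityKind.QUANTITATIVE,
            ki_nM=float(m.group("ki")),
            sem_nM=float(m.group("sem")),
        )
    m = _PERCENT_RE.match(norm)
    if m:
        pct = float(m.group("pct"))
        if pct < 0:
            raise ValidationError(f"negative percent displacement: {text!r}")
        return AffinityEntry(
            receptor=receptor, kind=AffinityKind.PERCENT, percent_at_1uM=pct
        )
    raise ParseError(f"unrecognized affinity cell {text!r} for receptor {receptor.value}")


def assemble_smiles(r2: str, r4: str, r6: str) -> str:
    """Build the canonical SMILES of a 2-amino-pyrimidine-5-carbonitrile.

    The scaffold carries the R2 amine at C2, the R4 group at C4, the R6
    group at C6 and a nitrile at C5.  Canonicalization is delegated to
    RDKit, so atom-order permutations of the same molecule collapse to one
    string.
    """
    try:
        r2_frag = R2_VOCABULARY[r2]
    except KeyError:
        raise ParseError(f"unknown R2 substituent code {r2!r}") from None
    frags = []
    for name, code in (("R4", r4), ("R6", r6)):
        try:
            frags.append(R4_R6_VOCABULARY[code])
        except KeyError:
            raise ParseError(f"unknown {name} substituent code {code!r}") from None
    raw = f"N#Cc1c(-{frags[0]})nc({r2_frag})nc1-{frags[1]}"
    mol = Chem.MolFromSmiles(raw)
    if mol is None:  # pragma: no cover - vocabulary fragments are all valid
        raise ParseError(f"assembled SMILES failed to parse: {raw!r}")
    return Chem.MolToSmiles(mol)


_AFFINITY_COLUMNS = {
    "a1": Receptor.A1,
    "a2a": Receptor.A2A,
    "a2b": Receptor.A2B,
    "a3": Receptor.A3,
}

_REFERENCE_IDS = {"XAC", "DPCPX", "ZM241385"}


def packaged_dataset_path() -> Path:
    """Filesystem path of the transcribed binding-table CSV shipped with
    the package."""
    return Path(resources.files("adenofep").joinpath("data/compounds.csv"))


def load_compound_table(path: str | Path | None = None) -> CompoundTable:
    """Load (and fully validate) a compound table CSV.

    With no argument the packaged transcription of the library's binding
    tables is loaded.  Every affinity cell goes through
    :func:`parse_affinity_cell`; rows lacking a SMILES get one assembled
    from their substituent codes.
    """
    if path is None:
        path = packaged_dataset_path()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"compound_id", "alt_label", "series", "r2", "r4", "r6", "smiles"}
    required |= set(_AFFINITY_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"dataset missing column(s): {sorted(missing)}")

    records: list[CompoundRecord] = []
    references: list[ReferenceRecord] = []
    for _, row in df.iterrows():
        cid = row["compound_id"].strip()
        affinities = {
            rec: parse_affinity_cell(row[col], rec)
            for col, rec in _AFFINITY_COLUMNS.items()
        }
        if cid in _REFERENCE_IDS or row["series"].strip() == "ref":
            references.append(
                ReferenceRecord(
                    compound_id=cid,
                    smiles=row["smiles"].strip() or None,
                    affinities=affinities,
                )
            )
            continue
        smiles = row["smiles"].strip() or assemble_smiles(
            row["r2"].strip(), row["r4"].strip(), row["r6"].strip()
        )
        records.append(
            CompoundRecord(
                compound_id=cid,
                alt_label=row["alt_label"].strip() or None,
                series=row["series"].strip(),
                r2=row["r2"].strip(),
                r4=row["r4"].strip(),
                r6=row["r6"].strip(),
                smiles=smiles,
                affinities=affinities,
            )
        )
    return CompoundTable(records=records, references=references)


def save_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a table back to the documented CSV schema (verbatim cells)."""

    def cell(entry: AffinityEntry) -> str:
        if entry.is_quantitative:
            return f"{entry.ki_nM:g} ± {entry.sem_nM:g}"
        return f"{entry.percent_at_1uM:g}%"

    rows = []
    for rec in table.records:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "alt_label": rec.alt_label or "",
                "series": rec.series,
                "r2": rec.r2,
                "r4": rec.r4,
                "r6": rec.r6,
                "smiles": rec.smiles,
                **{
                    col: cell(rec.affinities[r])
                    for col, r in _AFFINITY_COLUMNS.items()
                },
            }
        )
    for ref in table.references:
        rows.append(
            {
                "compound_id": ref.compound_id,
                "alt_label": "",
                "series": "ref",
                "r2": "",
                "r4": "",
                "r6": "",
                "smiles": ref.smiles or "",
                **{
                    col: cell(ref.affinities[r])
                    for col, r in _AFFINITY_COLUMNS.items()
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def export_structures(
    table: CompoundTable, path: str | Path, format: str = "smiles"
) -> int:
    """Write library structures (references excluded) to a SMILES list or
    an SDF v2000 file; the compound id is kept as the molecule title.

    Returns the number of records written.
    """
    path = Path(path)
    if format == "smiles":
        with open(path, "w") as fh:
            for rec in table.records:
                fh.write(f"{rec.compound_id}\t{rec.smiles}\n")
        return len(table.records)
    if format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in table.records:
                mol = Chem.MolFromSmiles(rec.smiles)
                mol.SetProp("_Name", rec.compound_id)
                writer.write(mol)
        finally:
            writer.close()
        return len(table.records)
    raise ValueError(f"unsupported export format {format!r}")
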