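"""Compound table I/O, CAS Registry Number handling, and structure standardization.

CAS Registry Numbers are three-segment identifiers ``A-B-C`` assigned roughly in
registration order, which makes them a usable chronological proxy for compound
collections.  The check digit ``C`` is a modulo-10 checksum over the digits of
``A`` and ``B``: with digits indexed 1.. from the rightmost digit of ``B``,
``C = (sum_i d_i * i) mod 10``.

Standardization keeps the largest fragment of multi-component inputs, rejects
inorganics and structures outside a molecular-weight window, and canonicalizes
the survivor as an isomeric SMILES — the identity key used everywhere downstream.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

#: Default element whitelist for the organic filter (plus the >=1 carbon rule).
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I", "Se"}
)


class Cohort(str, Enum):
    NP = "NP"
    SC = "SC"


class RejectReason(str, Enum):
    OK = "OK"
    NO_CAS = "NO_CAS"
    BAD_STRUCTURE = "BAD_STRUCTURE"
    INORGANIC = "INORGANIC"
    MW_LOW = "MW_LOW"
    MW_HIGH = "MW_HIGH"


class CasParseError(ValueError):
    """Raised for text that does not match the A-B-C CAS pattern."""


@dataclass(frozen=True, order=False)
class CasKey:
    """Parsed CAS number.  Ordering uses ``(major, minor)`` only; the check
    digit never participates (registration order is carried by the first two
    segments)."""

    major: int
    minor: int
    check: int
    checksum_valid: bool

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.major, self.minor)

    def __lt__(self, other: "CasKey") -> bool:
        return self.sort_key < other.sort_key

    def __le__(self, other: "CasKey") -> bool:
        return self.sort_key <= other.sort_key


@dataclass(frozen=True)
class CompoundRecord:
    structure: str
    cas: str
    cohort: Cohort
    record_id: str


@dataclass(frozen=True)
class StandardizationOutcome:
    kept: bool
    reason: RejectReason
    structure: str | None = None


@dataclass(frozen=True)
class StandardizeConfig:
    mw_min: float = 70.0
    mw_max: float = 2000.0
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS


@dataclass
class ReadResult:
    """Records read from a table plus the attrition bookkeeping the run
    manifest needs."""

    records: list[CompoundRecord] = field(default_factory=list)
    n_rows: int = 0
    n_dropped_bad_cas: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def cas_check_digit(major: int, minor: int) -> int:
    """Checksum over the digits of ``major`` then zero-padded two-digit
    ``minor``, weighted 1.. from the rightmost digit."""
    digits = f"{major}{minor:02d}"
    return sum(int(d) * i for i, d in enumerate(reversed(digits), start=1)) % 10


def parse_cas(text: str) -> CasKey:
    if not text:
        raise CasParseError("empty CAS string")
    m = _CAS_RE.match(text.strip())
    if m is None:
        raise CasParseError(f"malformed CAS Registry Number: {text!r}")
    major, minor, check = int(m.group(1)), int(m.group(2)), int(m.group(3))
    return CasKey(major, minor, check, checksum_valid=(cas_check_digit(major, minor) == check))


def format_cas(key: CasKey) -> str:
    return f"{key.major}-{key.minor:02d}-{key.check}"


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    # tie-break: heavy atoms, then MW, then canonical SMILES (lexicographic)
    def key(f: Chem.Mol):
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f))

    return max(frags, key=key)


def standardize(
    record: CompoundRecord, config: StandardizeConfig = StandardizeConfig()
) -> StandardizationOutcome:
    """Largest-fragment selection, organic filter, MW window.

    The MW window is inclusive at both ends: the source procedure removes
    strictly small (<70 Da) and strictly large (>2000 Da) molecules, so
    boundary values are kept.
    """
    if not record.cas or not record.cas.strip():
        return StandardizationOutcome(False, RejectReason.NO_CAS)
    mol = Chem.MolFromSmiles(record.structure)
    if mol is None:
        return StandardizationOutcome(False, RejectReason.BAD_STRUCTURE)
    mol = _largest_fragment(mol)
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= config.allowed_elements:
        return StandardizationOutcome(False, RejectReason.INORGANIC)
    mw = Descriptors.MolWt(mol)
    if mw < config.mw_min:
        return StandardizationOutcome(False, RejectReason.MW_LOW)
    if mw > config.mw_max:
        return StandardizationOutcome(False, RejectReason.MW_HIGH)
    return StandardizationOutcome(True, RejectReason.OK, Chem.MolToSmiles(mol))


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"smi", "smiles", "txt"}:
        return "smi"
    if suffix in {"sdf", "mol", "sd"}:
        return "sdf"
    if suffix in {"csv", "tsv"}:
        return "csv"
    raise ValueError(f"cannot infer compound-table format from {path.name!r}")


def _coerce_cohort(token: str | None, default: Cohort | None) -> Cohort:
    if token:
        return Cohort(token.strip().upper())
    if default is None:
        raise ValueError("row carries no cohort label and no default cohort was given")
    return default


def read_compound_table(
    path: str | Path,
    format: str | None = None,
    cohort: Cohort | None = None,
    cas_tag: str = "CAS",
    id_prefix: str | None = None,
) -> ReadResult:
    """Read a .smi / .csv / SDF compound table into :class:`CompoundRecord`.

    ``.smi``: whitespace-delimited ``SMILES CAS [cohort]``.  ``.csv``: named
    columns (``smiles``/``structure``, ``cas``, optional ``cohort``).  SDF:
    V2000 blocks with the CAS number in property tag ``cas_tag``.  Rows whose
    CAS fails to parse are dropped and counted, never fatal.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    prefix = id_prefix if id_prefix is not None else path.stem
    result = ReadResult()

    def add(structure: str, cas_text: str, cohort_token: str | None, row_no: int) -> None:
        result.n_rows += 1
        try:
            parse_cas(cas_text)
        except CasParseError:
            result.n_dropped_bad_cas += 1
            return
        result.records.append(
            CompoundRecord(
                structure=structure,
                cas=cas_text.strip(),
                cohort=_coerce_cohort(cohort_token, cohort),
                record_id=f"{prefix}:{row_no}",
            )
        )

    if fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 2:
                    result.n_rows += 1
                    result.n_dropped_bad_cas += 1
                    continue
                add(parts[0], parts[1], parts[2] if len(parts) > 2 else None, i)
    elif fmt == "csv":
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            cols = {c.lower(): c for c in reader.fieldnames or []}
            struct_col = cols.get("smiles") or cols.get("structure")
            cas_col = cols.get("cas")
            if struct_col is None or cas_col is None:
                raise ValueError(
                    f"{path.name}: need a smiles/structure column and a cas column, "
                    f"found {reader.fieldnames}"
                )
            cohort_col = cols.get("cohort")
            for i, row in enumerate(reader):
                add(row[struct_col], row[cas_col] or "", row.get(cohort_col or "", None), i)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                result.n_rows += 1
                result.n_dropped_bad_cas += 1
                continue
            cas_text = mol.GetProp(cas_tag) if mol.HasProp(cas_tag) else ""
            token = mol.GetProp("cohort") if mol.HasProp("cohort") else None
            add(Chem.MolToSmiles(mol), cas_text, token, i)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    if result.n_dropped_bad_cas:
        logger.info(
            "%s: dropped %d/%d rows with unparsable CAS",
            path.name,
            result.n_dropped_bad_cas,
            result.n_rows,
        )
    return result


def write_smi(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.structure}\t{r.cas}\t{r.cohort.value}\n")


def dataclasses_replace_structure(record: CompoundRecord, structure: str) -> CompoundRecord:
    """Copy of ``record`` with a new (e.g. standardized or deglycosylated)
    structure string."""
    return CompoundRecord(
        structure=structure, cas=record.cas, cohort=record.cohort, record_id=record.record_id
    )


def mol_from_record(record: CompoundRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.structure)
    if mol is None:
        raise ValueError(f"record {record.record_id}: unparsable structure")
    return mol


def sort_records(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Chronological (CAS-key) order, ties broken by record_id for stability."""

    def key(r: CompoundRecord):
        # hot path: avoid full CasKey construction for large cohorts
        major, minor, _ = r.cas.split("-")
        return (int(major), int(minor), r.record_id)

    return sorted(records, key=key)
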