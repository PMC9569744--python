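"""Readers and writers for the interchange formats.

All tables are UTF-8, tab-separated, with ``#``-prefixed provenance
header lines of the form ``# key=value``.  Residue coordinates in files
are 1-based inclusive (the UniProt convention); section indices are
0-based (the array convention).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .chem import CANONICAL_AA, ChainRange, ProteinRecord
from .mapping import Pattern2DE, SectionScheme, VirtualSpot
from .quantify import PsmRow

logger = logging.getLogger("virtual2de")

PATTERN_SCHEMA = "v2de-pattern/1"

__all__ = [
    "read_fasta",
    "read_chain_table",
    "load_records",
    "load_plasma_fixtures",
    "read_psm_table",
    "write_psm_table",
    "write_peptide_table",
    "write_pattern",
    "read_pattern",
    "RunConfig",
]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA with UniProt-style headers.

    ``sp|ACCESSION|ENTRY_NAME description`` headers are parsed into
    accession and entry name; any other header falls back to the first
    token as the accession.  Duplicate accessions and non-canonical
    residues are errors naming the record.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        parts = rec.id.split("|")
        if len(parts) >= 3 and parts[0] in ("sp", "tr"):
            accession, entry_name = parts[1], parts[2]
        else:
            accession, entry_name = rec.id, rec.id
        if accession in seen:
            raise ValueError(
                f"duplicate accession {accession} (records {seen[accession]} and {n})"
            )
        seen[accession] = n
        seq = str(rec.seq).upper()
        bad = [aa for aa in set(seq) if aa not in CANONICAL_AA]
        if bad:
            raise ValueError(f"{accession}: non-canonical residues {sorted(bad)}")
        records.append(ProteinRecord(accession=accession, entry_name=entry_name, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_chain_table(path: str | Path) -> dict[str, list[ChainRange]]:
    """Sidecar chain annotations: accession, chain_name, start, end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["accession", "chain_name", "start", "end"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"chain table missing column {col!r}")
    out: dict[str, list[ChainRange]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.accession), []).append(
            ChainRange(name=str(row.chain_name), start=int(row.start), end=int(row.end))
        )
    return out


def load_records(
    fasta_path: str | Path, chain_table_path: str | Path | None = None
) -> list[ProteinRecord]:
    """FASTA records with chain annotations merged from the sidecar."""
    records = read_fasta(fasta_path)
    if chain_table_path is not None:
        chains = read_chain_table(chain_table_path)
        for rec in records:
            rec.chains = chains.get(rec.accession, [])
            rec.__post_init__()  # re-validate chain bounds
    return records


def load_plasma_fixtures() -> list[ProteinRecord]:
    """The packaged classical-plasma-protein records with mature chains."""
    data = resources.files("virtual2de") / "data"
    with resources.as_file(data / "plasma_chains.fasta") as fasta, resources.as_file(
        data / "plasma_chains_annotations.tsv"
    ) as sidecar:
        return load_records(fasta, sidecar)


_PSM_REQUIRED = ["section_id", "accession", "peptide", "mods", "score", "is_unique"]


def read_psm_table(path: str | Path, max_malformed_fraction: float = 0.01) -> list[PsmRow]:
    """Read a per-section peptide-identification table.

    Extra columns are preserved as opaque metadata on each row.
    Malformed rows are logged and counted; the run aborts when they
    exceed ``max_malformed_fraction`` of the table.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in _PSM_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    extra_cols = [c for c in df.columns if c not in _PSM_REQUIRED]
    rows: list[PsmRow] = []
    malformed = 0
    for i, rec in enumerate(df.to_dict("records")):
        try:
            rows.append(
                PsmRow(
                    section_id=rec["section_id"],
                    accession=rec["accession"],
                    peptide=rec["peptide"],
                    mod_string=rec["mods"],
                    score=float(rec["score"]),
                    is_unique=rec["is_unique"].strip().lower() in ("1", "true", "yes"),
                    extra=tuple((c, rec[c]) for c in extra_cols),
                )
            )
        except (ValueError, KeyError) as exc:
            malformed += 1
            logger.warning("malformed PSM row %d: %s", i + 2, exc)
    total = len(df)
    if total and malformed / total > max_malformed_fraction:
        raise ValueError(
            f"{malformed} of {total} PSM rows malformed "
            f"(> {max_malformed_fraction:.0%} threshold); aborting"
        )
    return rows


def write_psm_table(rows: list[PsmRow], path: str | Path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(_PSM_REQUIRED) + "\n")
        for r in rows:
            fh.write(
                f"{r.section_id}\t{r.accession}\t{r.peptide}\t{r.mod_string}\t"
                f"{r.score:g}\t{str(r.is_unique).lower()}\n"
            )


def write_peptide_table(peptides, path: str | Path, chain: str = "") -> None:
    """Digest results: chain, start, end, sequence, missed_cleavages, masses."""
    with open(path, "w") as fh:
        fh.write("chain\tstart\tend\tsequence\tmissed_cleavages\tmass_avg\tmass_mono\n")
        for p in peptides:
            fh.write(
                f"{chain}\t{p.start}\t{p.end}\t{p.sequence}\t{p.missed_cleavages}\t"
                f"{p.mass_avg:.4f}\t{p.mass_mono:.4f}\n"
            )


# ---------------------------------------------------------------------------
# pattern round trip

_PATTERN_COLS = "accession\trow\tcol\tpi_low\tpi_high\tmw\tempai"


def _pattern_body(pattern: Pattern2DE) -> str:
    lines = [_PATTERN_COLS]
    for s in sorted(pattern.spots, key=lambda t: (t.accession, t.section)):
        lines.append(
            f"{s.accession}\t{s.section[0]}\t{s.section[1]}\t"
            f"{s.pi_window[0]:.6f}\t{s.pi_window[1]:.6f}\t{s.mw_value:.4f}\t{s.empai:.6f}"
        )
    return "\n".join(lines) + "\n"


def write_pattern(pattern: Pattern2DE, path: str | Path) -> None:
    """Write a pattern table with provenance header and body checksum."""
    body = _pattern_body(pattern)
    sch = pattern.scheme
    with open(path, "w") as fh:
        fh.write(f"# schema={PATTERN_SCHEMA}\n")
        fh.write(f"# scheme_mode={sch.mode}\n")
        fh.write(f"# col_unit={sch.col_unit}\n")
        fh.write(f"# col_edges={','.join(repr(float(e)) for e in sch.col_edges)}\n")
        if sch.row_edges is not None:
            fh.write(f"# row_unit={sch.row_unit}\n")
            fh.write(f"# row_edges={','.join(repr(float(e)) for e in sch.row_edges)}\n")
        for k, v in pattern.provenance.items():
            fh.write(f"# {k}={v}\n")
        fh.write(f"# checksum=sha256:{hashlib.sha256(body.encode()).hexdigest()}\n")
        fh.write(body)


def read_pattern(path: str | Path) -> Pattern2DE:
    """Read a pattern table; lossless inverse of :func:`write_pattern`.

    A schema-version mismatch is an error; a checksum mismatch is
    logged as a warning (the data may have been edited by hand).
    """
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# ") and "=" in line:
                k, v = line[2:].rstrip("\n").split("=", 1)
                header[k] = v
            else:
                body_lines.append(line)
    schema = header.pop("schema", None)
    if schema != PATTERN_SCHEMA:
        raise ValueError(f"pattern schema mismatch: {schema!r} != {PATTERN_SCHEMA!r}")
    body = "".join(body_lines)
    declared = header.pop("checksum", "")
    actual = "sha256:" + hashlib.sha256(body.encode()).hexdigest()
    if declared and declared != actual:
        logger.warning("pattern checksum mismatch in %s (edited by hand?)", path)

    scheme = SectionScheme(
        mode=header.pop("scheme_mode"),
        col_edges=tuple(float(x) for x in header.pop("col_edges").split(",")),
        row_edges=(
            tuple(float(x) for x in header.pop("row_edges").split(","))
            if "row_edges" in header
            else None
        ),
        col_unit=header.pop("col_unit"),
        row_unit=header.pop("row_unit", None),
    )
    spots = []
    lines = [ln for ln in body.splitlines() if ln.strip()]
    for ln in lines[1:]:
        acc, row, col, lo, hi, mw, em = ln.split("\t")
        spots.append(
            VirtualSpot(
                accession=acc, section=(int(row), int(col)),
                pi_window=(float(lo), float(hi)), mw_value=float(mw),
                empai=float(em),
            )
        )
    return Pattern2DE(spots=spots, scheme=scheme, provenance=header)


@dataclass
class RunConfig:
    """Effective run configuration; serialized next to every output."""

    fasta: str | None = None
    annotations: str | None = None
    psm: str | None = None
    output_dir: str = "."
    pka_set: str = "bjellqvist"
    window_min_mass: float = 500.0
    window_max_mass: float = 4500.0
    window_min_length: int = 6
    window_max_length: int = 50
    min_unique: int = 2
    score_threshold: float = 0.0
    scheme: str = "strip36"
    strip_length_cm: float = 18.0
    pi_tol: float = 0.25
    mw_tol_fraction: float = 0.1
    seed: int = 0
    version: str = "0.1.0"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras = extras
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extras"}
        data.update(self.extras)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
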