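"""Readers/writers for the plain-text dialects the pipeline speaks.

FASTA (60-column wrap, description after the first whitespace), peak lists as
two-column whitespace/TSV text with ``#`` comments, MGF with a singly-charged
assumption, TSV reports, and newick trees.  Machine outputs use 0-based
half-open coordinates; human-readable reports are 1-based and say so in their
headers.  Every report written by the CLI carries a header comment with the
tool version and the hash of the active configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .denovo import MsMsSpectrum
from .peaks import PeakList

__all__ = [
    "ParseError",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_peaklist",
    "write_peaklist",
    "read_mgf",
    "write_mgf",
    "read_newick",
    "write_newick",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending record/line."""


@dataclass
class RunConfig:
    """Tolerances, enzyme options and alignment parameters for one run.

    The defaults reproduce the study-facing behaviour: 0.3 Da peak pairing,
    0.05 Da fragment matching, 0.7 Da intact-mass check, trypsin K/R-P block
    off, EMBOSS-default alignment parameters and the six-Cys loop template.
    """

    pairing_tol: float = 0.3
    fragment_tol: float = 0.05
    mass_check_tol: float = 0.7
    resolve_tol: float = 0.2
    trypsin_proline_block: bool = False
    gap_open: float = 10.0
    gap_extend: float = 0.5
    evalue_cutoff: float = 0.001
    seed: int = 0
    verbosity: int = 1

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def header_comment(config: RunConfig | None = None) -> str:
    from . import __version__

    h = config.config_hash() if config else "default"
    return f"# crpkit {__version__} config={h}\n"


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, description, sequence) triples from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append((rec.id, desc, str(rec.seq).upper()))
    return records


def write_fasta(records, path: str | Path, wrap: int = 60) -> None:
    """Write (id, description, sequence) triples, wrapped at ``wrap`` columns."""
    seqs = [
        SeqRecord(Seq(seq), id=name, description=desc)
        for name, desc, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def read_peaklist(path: str | Path, label: str = "native") -> PeakList:
    """Two-column (m/z, intensity) text; '#' starts a comment."""
    mz, inten = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        fields = body.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'm/z intensity', got {line!r}")
        try:
            mz.append(float(fields[0]))
            inten.append(float(fields[1]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric peak {line!r}") from None
    return PeakList(np.array(mz), np.array(inten), label)


def write_peaklist(pl: PeakList, path: str | Path, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config))
        fh.write(f"# label={pl.label}  columns: m/z<TAB>intensity\n")
        for m, i in zip(pl.mz, pl.intensity):
            fh.write(f"{m:.5f}\t{i:.3f}\n")


def read_mgf(path: str | Path) -> list[MsMsSpectrum]:
    """MGF spectra (BEGIN IONS/PEPMASS/END IONS), charge assumed 1+.

    PEPMASS is taken as the singly-protonated precursor m/z.  A block without
    PEPMASS is a parse error naming the block.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                title = params.get("title", f"block {idx + 1}")
                raise ParseError(f"{path}: spectrum {title!r} has no PEPMASS")
            spectra.append(
                MsMsSpectrum(
                    float(pepmass[0]),
                    PeakList(entry["m/z array"], entry["intensity array"], "msms"),
                )
            )
    return spectra


def write_mgf(spectra: list[MsMsSpectrum], path: str | Path,
              titles: list[str] | None = None) -> None:
    entries = []
    for i, s in enumerate(spectra):
        entries.append(
            {
                "m/z array": s.peaks.mz,
                "intensity array": s.peaks.intensity,
                "params": {
                    "title": titles[i] if titles else f"spectrum_{i + 1}",
                    "pepmass": s.precursor_mh,
                    "charge": "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_newick(path: str | Path):
    from skbio.tree import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")
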