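"""File I/O: FASTA, GFF3, MGF, TSV peak lists and JSON/TSV reports.

GFF3 on disk is 1-based closed (per the format); everything in memory is
0-based half-open.  The GFF3 ``type`` column carries the ``lanM`` marker for
hallmark loci and the attribute column preserves feature ids.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .mining import Feature, GenomeRecord
from .spectra import Peak, Spectrum

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "load_genome",
    "read_mgf_spectra",
    "write_mgf_spectra",
    "read_peaks_tsv",
    "write_peaks_tsv",
    "mgf_peaks",
    "write_json_report",
    "write_tsv_table",
]

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Contig id -> sequence for every record in a FASTA file."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: PathLike) -> List[Feature]:
    """Parse a GFF3 file into features (converted to 0-based half-open)."""
    feats: List[Feature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            attributes = _parse_attributes(attrs)
            fid = attributes.get("ID", f"feature_{ln}")
            feats.append(
                Feature(
                    feature_id=fid,
                    contig=contig,
                    start=int(start) - 1,  # 1-based closed -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    type=ftype,
                    attributes=attributes,
                )
            )
    return feats


def write_gff3(features: Sequence[Feature], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.feature_id)
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        "lanmine",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attr_text,
                    ]
                )
                + "\n"
            )


def load_genome(
    fasta_path: PathLike, gff_path: PathLike
) -> List[GenomeRecord]:
    """Assemble GenomeRecords from a FASTA file and its GFF3 annotations."""
    seqs = read_fasta(fasta_path)
    feats = read_gff3(gff_path)
    records = []
    for contig, seq in seqs.items():
        ann = tuple(f for f in feats if f.contig == contig)
        records.append(GenomeRecord(contig=contig, sequence=seq, annotations=ann))
    return records


def read_mgf_spectra(path: PathLike) -> List[Spectrum]:
    """Read MS/MS spectra (or MS1 peak lists) from Mascot Generic Format."""
    spectra: List[Spectrum] = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            prec_mz = float(pepmass[0]) if pepmass else None
            charge = params.get("charge")
            prec_z = int(charge[0]) if charge else None
            mzs = entry["m/z array"]
            intens = entry.get("intensity array")
            if intens is None or len(intens) != len(mzs):
                intens = np.zeros_like(mzs)
            peaks = tuple(
                Peak(float(m), float(i)) for m, i in zip(mzs, intens)
            )
            spectra.append(
                Spectrum(
                    peaks=peaks,
                    precursor_mz=prec_mz,
                    precursor_charge=prec_z,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf_spectra(spectra: Sequence[Spectrum], path: PathLike) -> None:
    entries = []
    for sp in spectra:
        params: Dict[str, object] = {"title": sp.title}
        if sp.precursor_mz is not None:
            params["pepmass"] = sp.precursor_mz
        if sp.precursor_charge is not None:
            params["charge"] = sp.precursor_charge
        entries.append(
            {
                "m/z array": np.array([p.mz for p in sp.peaks]),
                "intensity array": np.array([p.intensity for p in sp.peaks]),
                "params": params,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def mgf_peaks(path: PathLike) -> List[Peak]:
    """Flatten an MGF file into one MS1 peak list (precursor-level peaks).

    Each MGF block contributes its PEPMASS as a peak when present (charge
    from the CHARGE line); blocks without PEPMASS contribute their raw
    peaks.
    """
    peaks: List[Peak] = []
    for sp in read_mgf_spectra(path):
        if sp.precursor_mz is not None:
            peaks.append(
                Peak(sp.precursor_mz, 0.0, sp.precursor_charge)
            )
        else:
            peaks.extend(sp.peaks)
    return peaks


def read_peaks_tsv(path: PathLike) -> List[Peak]:
    """Plain peak list: two or three columns (m/z, intensity[, charge])."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            mz = float(cols[0])
            inten = float(cols[1]) if len(cols) > 1 and cols[1] else 0.0
            z = int(cols[2]) if len(cols) > 2 and cols[2] else None
            peaks.append(Peak(mz, inten, z))
    return peaks


def write_peaks_tsv(peaks: Sequence[Peak], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#mz\tintensity\tcharge\n")
        for p in peaks:
            z = "" if p.charge is None else str(p.charge)
            fh.write(f"{p.mz:.6f}\t{p.intensity:.4f}\t{z}\n")


def write_json_report(report: object, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv_table(
    rows: Sequence[Dict[str, object]], path: PathLike
) -> None:
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
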