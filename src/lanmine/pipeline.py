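"""End-to-end orchestration: mine -> link -> ring topology, with reports.

The pipeline composes the module operations exactly as a manual analysis
would: six-frame ORF mining around every annotated lanM locus, precursor
filtering and leader/core split enumeration, MS1 matching of anticipated
modified species, and — when MS/MS spectra are supplied — ring-topology
scoring of the linked species.  Stages whose inputs are absent are skipped
and marked "not run" in the report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import io as lio
from . import mining, ms1, rings
from .chem import ModificationSet
from .ms1 import ModificationSpace, PeptideSpecies
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """One or more invalid configuration keys (all listed in the message)."""


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one pipeline run.

    Defaults mirror the mining and matching conventions documented on each
    module: 10 nearest ORFs, precursor length < 100 aa, Cys + Ser/Thr in
    the C-terminal 20 residues, 6 kb window, 10 ppm tolerances.
    """

    fasta: Optional[str] = None
    gff: Optional[str] = None
    ms1_peaks: Optional[str] = None  # MGF or TSV
    ms2_spectra: Optional[str] = None  # MGF

    window_bp: int = 6000
    k_adjacent: int = 10
    max_len: int = 100
    cterm_window: int = 20
    min_orf_len: int = 20
    max_orf_len: int = 200
    min_core: int = 5
    max_core: int = 30

    max_dehydrations: object = "auto"
    allow_methylation: Optional[bool] = None  # None = from GFF3 annotation
    max_methylations: int = 1
    allow_dehydrogenation: bool = False
    max_dehydrogenations: int = 1
    charges: Tuple[int, ...] = (1, 2, 3)

    tol_ppm_ms1: float = 10.0
    tol_ppm_ms2: float = 10.0
    fragmentation_mode: str = "cs-rupture"  # or "suppress"
    desulfurize_met: bool = False

    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        errors = []
        if self.tol_ppm_ms1 <= 0:
            errors.append(f"tol_ppm_ms1 must be > 0, got {self.tol_ppm_ms1}")
        if self.tol_ppm_ms2 <= 0:
            errors.append(f"tol_ppm_ms2 must be > 0, got {self.tol_ppm_ms2}")
        if self.k_adjacent < 1:
            errors.append(f"k_adjacent must be >= 1, got {self.k_adjacent}")
        if self.fragmentation_mode not in ("cs-rupture", "suppress"):
            errors.append(
                f"fragmentation_mode must be cs-rupture|suppress, "
                f"got {self.fragmentation_mode!r}"
            )
        if self.min_core > self.max_core:
            errors.append("min_core must be <= max_core")
        if errors:
            raise ConfigError("; ".join(errors))


_INT_KEYS = {
    "window_bp", "k_adjacent", "max_len", "cterm_window", "min_orf_len",
    "max_orf_len", "min_core", "max_core", "max_methylations",
    "max_dehydrogenations", "seed",
}
_FLOAT_KEYS = {"tol_ppm_ms1", "tol_ppm_ms2"}
_BOOL_KEYS = {"allow_dehydrogenation", "desulfurize_met"}


def validate_config(raw: Dict[str, object]) -> RunConfig:
    """Build a RunConfig from a raw mapping, rejecting unknown keys.

    Every offending key is collected and reported in one aggregated error.
    """
    known = {f.name for f in fields(RunConfig)}
    errors = []
    clean: Dict[str, object] = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"unknown key {key!r}")
            continue
        try:
            if key in _FLOAT_KEYS and isinstance(value, (int, float)) and not isinstance(value, bool) and value <= 0:
                raise ValueError(f"{key} must be > 0, got {value}")
            if key in _INT_KEYS:
                if isinstance(value, bool) or not isinstance(value, (int, float)) or (
                    isinstance(value, float) and value != int(value)
                ):
                    raise TypeError(f"{key} must be an integer, got {value!r}")
                clean[key] = int(value)
            elif key in _FLOAT_KEYS:
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise TypeError(f"{key} must be a number, got {value!r}")
                clean[key] = float(value)
            elif key in _BOOL_KEYS:
                if not isinstance(value, bool):
                    raise TypeError(f"{key} must be a boolean, got {value!r}")
                clean[key] = value
            elif key == "charges":
                clean[key] = tuple(int(z) for z in value)  # type: ignore[arg-type]
            elif key == "max_dehydrations":
                if value != "auto" and (
                    isinstance(value, bool) or not isinstance(value, int)
                ):
                    raise TypeError(
                        f"max_dehydrations must be an int or 'auto', got {value!r}"
                    )
                clean[key] = value
            elif key == "allow_methylation":
                if value is not None and not isinstance(value, bool):
                    raise TypeError(
                        f"allow_methylation must be a boolean or null, got {value!r}"
                    )
                clean[key] = value
            else:
                clean[key] = value
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return RunConfig(**clean)
    except ConfigError:
        raise
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from None


def _config_dict(config: RunConfig) -> Dict[str, object]:
    d = asdict(config)
    d["charges"] = list(config.charges)
    return d


def _load_peaks(path: str):
    if path.lower().endswith((".mgf",)):
        return lio.mgf_peaks(path)
    return lio.read_peaks_tsv(path)


def _methylation_annotated(records: Sequence[mining.GenomeRecord]) -> bool:
    for rec in records:
        for f in rec.annotations:
            if str(f.attributes.get("methyltransferase", "")).lower() == "true":
                return True
    return False


def mine_candidates(
    records: Sequence[mining.GenomeRecord], config: RunConfig
) -> List[Tuple[mining.Feature, List[mining.PrecursorCandidate]]]:
    """Per lanM anchor: ORF scan, k-nearest selection, precursor filter."""
    out = []
    found_anchor = False
    for rec in records:
        for anchor in rec.features_of_type("lanM"):
            found_anchor = True
            orfs = mining.find_orfs(
                rec,
                anchor,
                min_len_aa=config.min_orf_len,
                max_len_aa=config.max_orf_len,
                window_bp=config.window_bp,
            )
            nearest = mining.select_adjacent(orfs, k=config.k_adjacent)
            cands = mining.filter_precursors(
                nearest, max_len=config.max_len, cterm_window=config.cterm_window
            )
            out.append((anchor, cands))
    if not found_anchor:
        raise ValueError("no lanM features present in the annotations")
    return out


def _topology_verdicts(
    link_report: List[dict],
    spectra: Sequence[Spectrum],
    config: RunConfig,
) -> List[dict]:
    verdicts = []
    for entry in link_report:
        for link in entry["links"]:
            mods = ModificationSet(
                n_dehydration=link["modifications"]["n_dehydration"],
                n_methylation=link["modifications"]["n_methylation"],
                n_dehydrogenation=link["modifications"]["n_dehydrogenation"],
            )
            species = PeptideSpecies(core=link["core"], mods=mods)
            n_links = mods.n_dehydration
            candidates = rings.enumerate_candidate_topologies(
                species.core, n_links
            )
            if not candidates:
                continue
            # spectra whose precursor matches this species at some charge
            matching = []
            for sp in spectra:
                if sp.precursor_mz is None:
                    matching.append(sp)
                    continue
                zs = (
                    (sp.precursor_charge,)
                    if sp.precursor_charge
                    else config.charges
                )
                for z in zs:
                    from .chem import ppm_error

                    if abs(ppm_error(sp.precursor_mz, species.mz(z))) <= max(
                        config.tol_ppm_ms1, config.tol_ppm_ms2
                    ):
                        matching.append(sp)
                        break
            for sp in matching:
                scores, indeterminate = rings.score_topologies(
                    sp,
                    species,
                    candidates,
                    tol_ppm=config.tol_ppm_ms2,
                    charges=tuple(z for z in config.charges if z <= 2),
                    mode=config.fragmentation_mode,
                )
                best = scores[0]
                verdicts.append(
                    {
                        "core": species.core,
                        "spectrum_title": sp.title,
                        "crosslinks": [list(l) for l in best.topology.crosslinks],
                        "classification": (
                            "indeterminate"
                            if indeterminate
                            else rings.classify_topology(best.topology)
                        ),
                        "indeterminate": indeterminate,
                        "n_discriminating": best.n_discriminating,
                        "coverage": round(best.coverage, 4),
                        "n_candidates": len(candidates),
                    }
                )
    return verdicts


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute mining -> MS1 linking -> topology inference per the config.

    Returns the JSON-ready run report.  Stages with absent inputs are
    skipped (an MS1-only run marks the topology section "not run"); hard
    errors (missing files, no lanM features, malformed inputs) raise.
    """
    if not config.fasta or not config.gff:
        raise ValueError("fasta and gff input paths are required")
    for path in (config.fasta, config.gff, config.ms1_peaks, config.ms2_spectra):
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    records = lio.load_genome(config.fasta, config.gff)
    mined = mine_candidates(records, config)

    candidate_rows = []
    all_candidates = []
    for anchor, cands in mined:
        for c in cands:
            all_candidates.append(c)
            candidate_rows.append(
                {
                    "anchor": anchor.feature_id,
                    "contig": c.orf.contig,
                    "start": c.orf.start,
                    "end": c.orf.end,
                    "strand": c.orf.strand,
                    "length_aa": c.orf.length_aa,
                    "distance_to_lanM": c.distance_to_lanM,
                    "precursor": c.aa_sequence,
                    "n_motif_hits": len(c.motif_hits),
                }
            )

    report: Dict[str, object] = {
        "schema_version": SCHEMA_VERSION,
        "config": _config_dict(config),
        "seed": config.seed,
        "candidates": candidate_rows,
    }

    if config.ms1_peaks:
        peaks = _load_peaks(config.ms1_peaks)
        allow_meth = config.allow_methylation
        if allow_meth is None:
            allow_meth = _methylation_annotated(records)
        space = ModificationSpace(
            max_dehydrations=config.max_dehydrations,  # type: ignore[arg-type]
            allow_methylation=allow_meth,
            max_methylations=config.max_methylations,
            allow_dehydrogenation=config.allow_dehydrogenation,
            max_dehydrogenations=config.max_dehydrogenations,
            charge_states=config.charges,
        )
        link_report = ms1.link_bgc_to_peaks(
            all_candidates,
            peaks,
            space,
            tol_ppm=config.tol_ppm_ms1,
            min_core=config.min_core,
            max_core=config.max_core,
        )
        report["links"] = link_report
        report["allow_methylation_effective"] = allow_meth
    else:
        report["links"] = "not run"

    if config.ms2_spectra and config.ms1_peaks:
        spectra = lio.read_mgf_spectra(config.ms2_spectra)
        report["topology"] = _topology_verdicts(
            report["links"], spectra, config  # type: ignore[arg-type]
        )
    else:
        report["topology"] = "not run"
    return report
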