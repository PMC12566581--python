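"""Readers and writers for the delimited and spectral formats the pipeline
touches: MSP/MGF fragment spectra (via matchms), feature tables, parent
registries and suspect lists as tab- or comma-delimited text, and flat
key=value run configuration files."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from matchms import Spectrum as _MatchmsSpectrum
from matchms.exporting import save_as_mgf, save_as_msp
from matchms.importing import load_from_mgf, load_from_msp

from .chem import ElementalFormula, parse_formula
from .filtering import FeatureTable
from .similarity import FragmentSpectrum

__all__ = [
    "ParentCompound",
    "Suspect",
    "RunConfig",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "read_registry",
    "write_registry",
    "read_suspects",
]


@dataclass(frozen=True)
class ParentCompound:
    """A registry row: one target parent compound."""

    name: str
    formula: ElementalFormula
    rt: Optional[float] = None


@dataclass(frozen=True)
class Suspect:
    """A suspect-list row: an expected metabolite from literature or a
    prediction tool."""

    name: str
    formula: ElementalFormula
    parent: str = ""
    source: str = "literature"


def _to_matchms(spectrum: FragmentSpectrum) -> _MatchmsSpectrum:
    metadata = {"precursor_mz": float(spectrum.precursor_mz)}
    if spectrum.name:
        metadata["compound_name"] = spectrum.name
    if spectrum.rt is not None:
        metadata["retention_time"] = float(spectrum.rt)
    return _MatchmsSpectrum(
        mz=np.array(spectrum.mzs, dtype=float),
        intensities=np.array(spectrum.intensities, dtype=float),
        metadata=metadata,
        metadata_harmonization=False,
    )


def _from_matchms(spectrum: _MatchmsSpectrum) -> FragmentSpectrum:
    meta = spectrum.metadata
    precursor = meta.get("precursor_mz") or meta.get("pepmass")
    if precursor is None:
        raise ValueError(
            f"spectrum {meta.get('compound_name', '?')!r} has no precursor m/z"
        )
    if isinstance(precursor, (tuple, list)):
        precursor = precursor[0]
    rt = meta.get("retention_time")
    return FragmentSpectrum(
        precursor_mz=float(precursor),
        peaks=tuple(zip(spectrum.peaks.mz, spectrum.peaks.intensities)),
        name=str(meta.get("compound_name", "") or ""),
        rt=float(rt) if rt is not None else None,
    )


def read_msp(path: Path) -> List[FragmentSpectrum]:
    return [_from_matchms(s) for s in load_from_msp(str(path)) if s is not None]


def write_msp(spectra: Sequence[FragmentSpectrum], path: Path) -> None:
    save_as_msp([_to_matchms(s) for s in spectra], str(path), mode="w")


def read_mgf(path: Path) -> List[FragmentSpectrum]:
    return [_from_matchms(s) for s in load_from_mgf(str(path)) if s is not None]


def write_mgf(spectra: Sequence[FragmentSpectrum], path: Path) -> None:
    path = Path(path)
    if path.exists():  # save_as_mgf appends; we want overwrite semantics
        path.unlink()
    save_as_mgf([_to_matchms(s) for s in spectra], str(path))


def _read_delimited(path: Path, sep: Optional[str]) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if "\t" in Path(path).read_text().splitlines()[0] else ","
    return pd.read_csv(path, sep=sep)


def read_feature_table(path: Path, sep: Optional[str] = None) -> FeatureTable:
    """Read a feature table whose header names sample roles
    (``rep_1``, ``blank_1``, ...); ``id``, ``mz``, ``rt`` and optional
    ``snr`` columns describe the features."""
    df = _read_delimited(path, sep)
    meta_cols = [c for c in ("id", "mz", "rt", "snr") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    features = df[meta_cols].set_index("id")
    intensities = df[sample_cols].set_index(features.index)
    roles = {
        c: "blank" if str(c).lower().startswith("blank") else "treatment"
        for c in sample_cols
    }
    return FeatureTable(features, intensities, roles)


def write_feature_table(table: FeatureTable, path: Path, sep: str = "\t") -> None:
    df = table.features.join(table.intensities)
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def read_registry(path: Path, sep: Optional[str] = None) -> List[ParentCompound]:
    df = _read_delimited(path, sep)
    out = []
    for _, row in df.iterrows():
        rt = row.get("rt")
        out.append(
            ParentCompound(
                name=str(row["name"]),
                formula=parse_formula(str(row["formula"])),
                rt=float(rt) if rt is not None and pd.notna(rt) else None,
            )
        )
    return out


def write_registry(parents: Sequence[ParentCompound], path: Path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {"name": p.name, "formula": p.formula.hill(), "rt": p.rt}
            for p in parents
        ]
    ).to_csv(path, sep=sep, index=False)


def read_suspects(path: Path, sep: Optional[str] = None) -> List[Suspect]:
    """Read a suspect list; rows with unparseable formulas are skipped with
    a warning rather than aborting the run."""
    import warnings

    df = _read_delimited(path, sep)
    out = []
    for _, row in df.iterrows():
        try:
            formula = parse_formula(str(row["formula"]))
        except ValueError as exc:
            warnings.warn(f"skipping suspect {row['name']!r}: {exc}")
            continue
        out.append(
            Suspect(
                name=str(row["name"]),
                formula=formula,
                parent=str(row.get("parent", "") or ""),
                source=str(row.get("source", "literature") or "literature"),
            )
        )
    return out


@dataclass
class RunConfig:
    """Serializable settings for one pipeline run; written alongside the
    outputs so any run can be reproduced bit-identically."""

    registry: str = ""
    feature_table: str = ""
    spectra: str = ""
    parent_only_spectra: str = ""
    suspects: str = ""
    rule_table: str = ""
    output_dir: str = "."
    adduct: str = "[M+H]+"
    presence_fraction: float = 0.5
    snr_min: float = 3.0
    fc_min: float = 2.0
    p_max: float = 0.05
    similarity_threshold: float = 0.4
    match_tol_ppm: float = 10.0
    db_tol_ppm: float = 25.0
    rule_depth: int = 1
    seed: int = 0

    def write(self, path: Path) -> None:
        lines = [f"{key} = {value}" for key, value in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: Path) -> "RunConfig":
        values: Dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs = {}
        for name, f in cls.__dataclass_fields__.items():
            if name not in values:
                continue
            if f.type in ("float", float):
                kwargs[name] = float(values[name])
            elif f.type in ("int", int):
                kwargs[name] = int(values[name])
            else:
                kwargs[name] = values[name]
        return cls(**kwargs)
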