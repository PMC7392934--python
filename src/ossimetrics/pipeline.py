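"""Study orchestration: specimens -> measurements -> species summaries.

A study is described by a YAML config listing specimen inputs (mask or
grayscale volume, optional mesh and landmark files, ossicle kind, side,
measured mass where available) and per-species constants (tympanic-membrane
area, cochlear and air impedances).  ``run_specimen`` produces one flat
record per specimen; ``aggregate`` emits mean +/- SD tables per
(species, ossicle) group, resolving the average density from mean mass over
mean volume — the convention used when only a subset of specimens was
weighed; ``reproduce_discussion`` evaluates the ideal-transformer model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import load_landmarks, load_volume, segment_window
from .mass_properties import mass_properties_from_mask
from .morphometry import characteristic_lengths
from .transformer import DEFAULT_SPECIES, TransformerParams, species_report

__all__ = [
    "SpecimenEntry",
    "StudyConfig",
    "run_specimen",
    "aggregate",
    "species_ratio",
    "reproduce_discussion",
    "run_study",
    "write_report",
]


@dataclass(frozen=True)
class SpecimenEntry:
    specimen_id: str
    species: str
    ossicle: str
    mask: str | None = None          # path to a binary mask volume
    volume: str | None = None        # path to a grayscale volume
    window: tuple = (250, 1000)      # grayscale window for `volume`
    landmarks: str | None = None
    spacing_mm: float | None = None
    mass_mg: float | None = None
    side: str = "right"


@dataclass(frozen=True)
class StudyConfig:
    specimens: tuple
    species: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        specimens = tuple(
            SpecimenEntry(
                specimen_id=str(e["id"]), species=e["species"],
                ossicle=e["ossicle"], mask=e.get("mask"),
                volume=e.get("volume"),
                window=tuple(e.get("window", (250, 1000))),
                landmarks=e.get("landmarks"),
                spacing_mm=e.get("spacing_mm"),
                mass_mg=e.get("mass_mg"), side=e.get("side", "right"))
            for e in raw.get("specimens", []))
        species = {
            name: TransformerParams(**params)
            for name, params in (raw.get("species") or {}).items()}
        return cls(specimens=specimens, species=species,
                   base_dir=path.parent)

    def config_hash(self) -> str:
        payload = json.dumps(
            [vars(s) for s in self.specimens], sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_specimen(entry: SpecimenEntry, base_dir=Path(".")) -> dict:
    """Measurements and unit-density inertial properties of one specimen.

    The inertia tensor is computed at unit density and rescaled during
    aggregation once the species-average density (mean mass / mean volume)
    is known; when the specimen has a measured mass, its own density m/V is
    recorded as well.  Errors are re-raised tagged with the specimen id.
    """
    base = Path(base_dir)
    try:
        if entry.mask is not None:
            vol = load_volume(base / entry.mask, spacing_mm=entry.spacing_mm)
            mask = vol if vol.is_mask() else segment_window(vol, 0.5,
                                                            np.inf)
        elif entry.volume is not None:
            gray = load_volume(base / entry.volume,
                               spacing_mm=entry.spacing_mm)
            mask = segment_window(gray, *entry.window)
        else:
            raise ValueError("specimen has neither a mask nor a volume")
        mp = mass_properties_from_mask(mask, density=1.0)

        record: dict = {
            "id": entry.specimen_id, "species": entry.species,
            "ossicle": entry.ossicle,
            "V": mp.volume,
            "I_MIN_unit": mp.i_min, "I_MED_unit": mp.i_med,
            "I_MAX_unit": mp.i_max,
        }
        if entry.mass_mg is not None:
            record["m"] = entry.mass_mg
            record["rho"] = entry.mass_mg / mp.volume
        if entry.landmarks is not None:
            lm = load_landmarks(base / entry.landmarks)
            record.update(characteristic_lengths(lm, entry.ossicle,
                                                 com=mp.com))
        return record
    except Exception as exc:
        raise type(exc)(
            f"specimen {entry.specimen_id!r}: {exc}") from exc


def aggregate(records, by=("species", "ossicle")) -> pd.DataFrame:
    """Mean +/- SD per group for every numeric quantity.

    Ratio quantities (keys containing '/') were computed per specimen, so
    their group mean is a mean of ratios; a ratio-of-means column is added
    alongside for each.  The group density `rho_from_means` is mean mass
    over mean volume, and the unit-density principal moments are rescaled by
    it into I_MIN/I_MED/I_MAX.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records to aggregate")
    by = [b for b in by if b in df.columns]
    numeric = df.select_dtypes(include=[np.number]).columns
    grouped = df.groupby(by, dropna=False)
    out = grouped[list(numeric)].agg(["mean", "std", "count"])
    out.columns = [f"{q}_{stat}" for q, stat in out.columns]

    for name in numeric:
        if "/" in name:
            num, den = name.split("/", 1)
            if num in numeric and den in numeric:
                out[f"{name}_ratio_of_means"] = (
                    out[f"{num}_mean"] / out[f"{den}_mean"])
    if "m_mean" in out.columns and "V_mean" in out.columns:
        out["rho_from_means"] = out["m_mean"] / out["V_mean"]
        for tag in ("I_MIN", "I_MED", "I_MAX"):
            col = f"{tag}_unit_mean"
            if col in out.columns:
                out[tag + "_mean"] = out[col] * out["rho_from_means"]
    return out


def species_ratio(summary: pd.DataFrame, numerator: str = "sheep",
                  denominator: str = "human") -> pd.DataFrame:
    """Cross-species ratio columns (mean_numerator / mean_denominator)."""
    levels = summary.index.get_level_values(0)
    num = summary[levels == numerator].droplevel(0)
    den = summary[levels == denominator].droplevel(0)
    cols = [c for c in summary.columns if c.endswith("_mean")]
    return (num[cols] / den[cols]).rename(
        columns={c: c.replace("_mean", f"_{numerator}/{denominator}")
                 for c in cols})


def reproduce_discussion(species: dict | None = None) -> pd.DataFrame:
    """The transformer-model comparison table with the default (human and
    sheep) parameterization, or any user-supplied species map."""
    if species is not None and len(species) == 0:
        return pd.DataFrame(
            columns=["area_ratio", "lever_ratio", "pressure_gain",
                     "lever_db", "z_tm", "energy_fraction"])
    return species_report(species)


def run_study(config: StudyConfig) -> dict:
    """Run every specimen, aggregate, and evaluate the transformer model."""
    records = [run_specimen(e, base_dir=config.base_dir)
               for e in config.specimens]
    summary = aggregate(records) if records else None
    transformer = reproduce_discussion(config.species or DEFAULT_SPECIES)
    return {"records": records, "summary": summary,
            "transformer": transformer}


def _df_to_markdown(df: pd.DataFrame) -> str:
    table = df.reset_index()
    header = "| " + " | ".join(str(c) for c in table.columns) + " |"
    sep = "|" + "|".join("---" for _ in table.columns) + "|"
    rows = []
    for _, row in table.iterrows():
        cells = [f"{v:.4g}" if isinstance(v, (int, float, np.floating))
                 else str(v) for v in row]
        rows.append("| " + " | ".join(cells) + " |")
    return "\n".join([header, sep, *rows]) + "\n"


def write_report(result: dict, out_dir, config: StudyConfig | None = None
                 ) -> None:
    """CSV + markdown report; deterministic (no timestamps), full precision
    in the CSVs, version and config hash in the markdown header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [f"# ossimetrics report (v{__version__})"]
    if config is not None:
        lines.append(f"config hash: `{config.config_hash()}`")
    if result.get("summary") is not None:
        result["summary"].to_csv(out / "summary.csv")
        lines += ["", "## Per-group summary", "",
                  _df_to_markdown(result["summary"])]
    result["transformer"].to_csv(out / "transformer.csv")
    lines += ["", "## Middle-ear transformer model", "",
              _df_to_markdown(result["transformer"])]
    (out / "report.md").write_text("\n".join(lines))
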