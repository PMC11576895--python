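"""Species physiology and the tight/leaky tissue-lumping scheme.

The minimal PBPK geometry collapses the body into plasma, lymph and two
lumped tissues.  Tissues whose capillaries have a small upper pore-size
limit (brain, muscle, skin, adipose) form the *tight* lump; every other
tissue is *leaky*.  Each lump keeps physiological vascular, endosomal and
interstitial volumes, a plasma flow and a lymph flow, so the reduced model
retains whole-body mass-balance semantics.

Per-tissue tables are plain CSV (``tissue,V_v_L,V_e_L,V_is_L,Q_L_per_h,
L_L_per_h``); species-level parameters live in a YAML file with units in
the key names.  Packaged mouse (28 g) and human (70 kg) defaults ship under
``mpbpk/data`` and are ordinary editable config, not code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "TIGHT_TISSUES",
    "SpeciesPhysiology",
    "lump_tissues",
    "recycling_clearance",
    "load_tissue_table",
    "load_species",
]

#: Tissues whose capillary pore-size upper limit is below ~5 nm.
TIGHT_TISSUES = frozenset({"brain", "muscle", "skin", "adipose"})

#: Recognised tissue vocabulary for per-tissue tables.
KNOWN_TISSUES = TIGHT_TISSUES | {
    "heart", "lung", "kidney", "liver", "small_intestine", "large_intestine",
    "gut", "stomach", "spleen", "pancreas", "bone", "thymus", "lymph_node",
    "testes", "ovaries", "other",
}

TISSUE_TABLE_COLUMNS = ["tissue", "V_v_L", "V_e_L", "V_is_L", "Q_L_per_h", "L_L_per_h"]


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Volumes (L), flows (L/h) and receptor/filtration constants for one species.

    ``tight``/``leaky`` sub-space volumes follow the two-pore mPBPK layout:
    vascular (``V_v``), endothelial endosomal (``V_e``) and interstitial
    (``V_is``) spaces per lump, plasma flow ``Q`` and lymph flow ``L``.
    ``V_ep`` is the endosomal volume of the systemic vascular endothelium
    nested inside the plasma compartment.  ``FcRn_total`` is the endosomal
    FcRn concentration (nM), identical in plasma and tissue endosomes.
    """

    species_name: str
    body_weight_kg: float
    V_p_L: float
    V_lymph_L: float
    V_ep_L: float
    V_v_tight_L: float
    V_e_tight_L: float
    V_is_tight_L: float
    Q_tight_L_per_h: float
    L_tight_L_per_h: float
    V_v_leaky_L: float
    V_e_leaky_L: float
    V_is_leaky_L: float
    Q_leaky_L_per_h: float
    L_leaky_L_per_h: float
    FcRn_total_nM: float
    GFR_L_per_h: float
    endosomal_transit_time_h: float
    sigma_L: float = 0.2

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name in ("species_name", "sigma_L"):
                continue
            if name == "FcRn_total_nM":  # zero models FcRn knockout
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value!r}")
                continue
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0.0 <= self.sigma_L < 1.0:
            raise ValueError(f"sigma_L must lie in [0, 1), got {self.sigma_L!r}")

    @property
    def L_total_L_per_h(self) -> float:
        return self.L_tight_L_per_h + self.L_leaky_L_per_h

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesPhysiology":
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SpeciesPhysiology":
        if isinstance(source, Path) or "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text))

    def with_overrides(self, **kwargs) -> "SpeciesPhysiology":
        return replace(self, **kwargs)


def recycling_clearance(V_endosome_L: float, transit_time_h: float) -> float:
    """Endosomal recycling clearance (L/h) = endosomal volume / transit time.

    An 8 min transit time is the default species configuration; the clearance
    scales linearly with the endosomal volume it serves.
    """
    if not V_endosome_L > 0:
        raise ValueError(f"V_endosome_L must be > 0, got {V_endosome_L!r}")
    if not transit_time_h > 0:
        raise ValueError(f"transit_time_h must be > 0, got {transit_time_h!r}")
    return V_endosome_L / transit_time_h


def lump_tissues(per_tissue_table: pd.DataFrame, *, species_params: dict) -> SpeciesPhysiology:
    """Collapse a per-tissue physiology table into the tight/leaky geometry.

    Parameters
    ----------
    per_tissue_table
        Columns ``tissue,V_v_L,V_e_L,V_is_L,Q_L_per_h,L_L_per_h``.  Must
        contain all four tight tissues (case-insensitive); every other row
        is summed into the leaky lump.
    species_params
        The non-tissue fields of :class:`SpeciesPhysiology` (species name,
        body weight, plasma/lymph/nested-endosome volumes, FcRn, GFR, ...).
    """
    df = per_tissue_table.copy()
    missing_cols = [c for c in TISSUE_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"per-tissue table is missing columns {missing_cols}")
    names = df["tissue"].astype(str).str.strip().str.lower()
    dup = names[names.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate tissue name in table: {dup.iloc[0]!r}")
    unknown = set(names) - KNOWN_TISSUES
    if unknown:
        raise ValueError(f"unknown tissue name in table: {sorted(unknown)[0]!r}")
    if (df[TISSUE_TABLE_COLUMNS[1:]] < 0).any().any():
        bad = names[(df[TISSUE_TABLE_COLUMNS[1:]] < 0).any(axis=1)].iloc[0]
        raise ValueError(f"negative physiological entry for tissue {bad!r}")
    missing_tight = TIGHT_TISSUES - set(names)
    if missing_tight:
        raise ValueError(f"missing tight tissue(s): {sorted(missing_tight)}")
    df = df.assign(_name=names).sort_values("_name")  # order-independent sums
    is_tight = df["_name"].isin(TIGHT_TISSUES).to_numpy()
    tight = df.loc[is_tight, TISSUE_TABLE_COLUMNS[1:]].sum()
    leaky = df.loc[~is_tight, TISSUE_TABLE_COLUMNS[1:]].sum()
    return SpeciesPhysiology(
        V_v_tight_L=float(tight["V_v_L"]),
        V_e_tight_L=float(tight["V_e_L"]),
        V_is_tight_L=float(tight["V_is_L"]),
        Q_tight_L_per_h=float(tight["Q_L_per_h"]),
        L_tight_L_per_h=float(tight["L_L_per_h"]),
        V_v_leaky_L=float(leaky["V_v_L"]),
        V_e_leaky_L=float(leaky["V_e_L"]),
        V_is_leaky_L=float(leaky["V_is_L"]),
        Q_leaky_L_per_h=float(leaky["Q_L_per_h"]),
        L_leaky_L_per_h=float(leaky["L_L_per_h"]),
        **species_params,
    )


def _read_packaged(name: str) -> str:
    return resources.files("mpbpk.data").joinpath(name).read_text()


def load_tissue_table(source: str | Path) -> pd.DataFrame:
    """Read a per-tissue CSV (``#`` lines are comments)."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return pd.read_csv(io.StringIO(text), comment="#")


def load_species(species: str = "mouse") -> SpeciesPhysiology:
    """Build a packaged species (``mouse`` or ``human``) from its shipped config."""
    try:
        params = yaml.safe_load(_read_packaged(f"{species}.yaml"))
        table = pd.read_csv(io.StringIO(_read_packaged(f"{species}_tissues.csv")), comment="#")
    except FileNotFoundError as err:  # pragma: no cover
        raise ValueError(f"no packaged physiology for species {species!r}") from err
    return lump_tissues(table, species_params=params)
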