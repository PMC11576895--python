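"""Synthetic observed-style PK datasets and ready-to-run study scenarios.

Calibration-grade antibody PK data are rarely redistributable, so every
fitting and validation pathway in this package is exercised against
datasets generated from the model itself: simulate a scenario, sample the
observables at assay-like times, optionally add multiplicative log-normal
noise (median preserved), and censor below an LLOQ.  The generator records
its own provenance (scenario, seed, noise) in the dataset metadata.

The packaged scenarios mirror the study conditions of the calibration and
evaluation cases: wild-type and FcRn-knockout mouse IgG at 8 mg/kg,
50/100/150 kDa size variants at 5 mg/kg, charge variants (-8/0/+5) at
10 mg/kg, an anti-CEA antibody with membrane-target TMDD at 1/10/25 mg/kg,
and an anti-TNF-alpha antibody in humans at 1/3/5 mg/kg.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compound import AntibodyDescriptor, TargetDescriptor
from .core import ModelParams, build_model_params
from .physiology import load_species
from .simulation import DoseSchedule, simulate

__all__ = ["NoiseModel", "ObservedDataset", "Scenario", "generate_pk_dataset",
           "scenario_fixtures", "load_scenario"]


@dataclass(frozen=True)
class NoiseModel:
    """Sampling design and measurement-noise description for one dataset.

    ``lognormal`` noise multiplies each concentration by ``exp(eps)`` with
    ``eps ~ N(0, ln(1+cv^2))``, preserving the median.  Values below the
    LLOQ are flagged as censored, never silently dropped.
    """

    kind: str = "none"  # "none" | "lognormal"
    cv: float = 0.15
    seed: int = 0
    sampling_times_h: tuple = (0.25, 1, 3, 8, 24, 48, 96, 168, 240, 336, 420, 504)
    lloq_nM: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass
class ObservedDataset:
    """(time, observable, value) records with provenance metadata."""

    data: pd.DataFrame  # time_h, observable, value, unit, censored
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metadata: {json.dumps(self.metadata)}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedDataset":
        text = Path(path).read_text()
        meta = {}
        for line in text.splitlines():
            if line.startswith("# metadata:"):
                meta = json.loads(line.split(":", 1)[1])
        return cls(data=pd.read_csv(io.StringIO(text), comment="#"), metadata=meta)

    @property
    def fit_frame(self) -> pd.DataFrame:
        """Uncensored rows only, as expected by the estimation module."""
        d = self.data
        return d[~d["censored"]][["time_h", "observable", "value"]].reset_index(drop=True)


def generate_pk_dataset(
    params: ModelParams,
    schedule: DoseSchedule,
    noise: NoiseModel,
    observables=("plasma", "tight_total", "leaky_total"),
) -> ObservedDataset:
    """Simulate, sample at the noise model's times, perturb and censor."""
    times = np.asarray(noise.sampling_times_h, dtype=float)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    prof = simulate(params, schedule, t_grid=t_grid)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for obs in observables:
        vals = np.interp(times, prof.t_h, prof.observable(obs))
        if noise.kind == "lognormal" and noise.cv > 0:
            sd = math.sqrt(math.log(1.0 + noise.cv**2))
            vals = vals * np.exp(rng.normal(0.0, sd, size=vals.shape))
        censored = (vals < noise.lloq_nM) if noise.lloq_nM is not None else np.zeros_like(vals, bool)
        rows.append(pd.DataFrame({"time_h": times, "observable": obs, "value": vals,
                                  "unit": "nM", "censored": censored}))
    meta = {"noise_kind": noise.kind, "cv": noise.cv, "seed": noise.seed,
            "lloq_nM": noise.lloq_nM, "antibody": params.antibody.name,
            "doses_nmol": list(prof.doses_nmol)}
    return ObservedDataset(data=pd.concat(rows, ignore_index=True), metadata=meta)


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A ready-to-run study configuration: species, compound, doses, overrides."""

    name: str
    species: str
    antibody: AntibodyDescriptor
    doses_mg_per_kg: tuple
    t_end_h: float
    target: TargetDescriptor | None = None
    overrides: dict = field(default_factory=dict)

    def build(self, dose_mg_per_kg: float | None = None,
              extra_overrides: dict | None = None) -> tuple[ModelParams, DoseSchedule]:
        """Resolve (ModelParams, DoseSchedule) for one dose level (default: first)."""
        dose = self.doses_mg_per_kg[0] if dose_mg_per_kg is None else dose_mg_per_kg
        phys = load_species(self.species)
        ov = dict(self.overrides)
        ov.update(extra_overrides or {})
        params = build_model_params(phys, self.antibody, self.target, overrides=ov)
        schedule = DoseSchedule.from_mg_per_kg(dose, phys.body_weight_kg, self.antibody.MW_Da)
        return params, schedule


def load_scenario(source: str | Path) -> Scenario:
    """Load one scenario from a YAML mapping (packaged name or file path)."""
    p = Path(str(source))
    if p.exists():
        raw = yaml.safe_load(p.read_text())
    else:
        text = resources.files("mpbpk.data.scenarios").joinpath(f"{source}.yaml").read_text()
        raw = yaml.safe_load(text)
    target = raw.get("target")
    return Scenario(
        name=raw["name"],
        species=raw["species"],
        antibody=AntibodyDescriptor.from_dict(raw["antibody"]),
        target=TargetDescriptor.from_dict(target) if target else None,
        doses_mg_per_kg=tuple(raw["doses_mg_per_kg"]),
        t_end_h=float(raw["t_end_h"]),
        overrides=dict(raw.get("overrides") or {}),
    )


_SCENARIO_NAMES = (
    "mouse_igg_wt",
    "mouse_igg_fcrn_ko",
    "mouse_igg_150kda",
    "mouse_igg_100kda",
    "mouse_fab_50kda",
    "mouse_igg_charge_neg8",
    "mouse_igg_charge_neutral",
    "mouse_igg_charge_pos5",
    "mouse_anti_cea",
    "human_anti_tnfa",
)


def scenario_fixtures() -> dict[str, Scenario]:
    """All packaged scenarios, keyed by name."""
    return {name: load_scenario(name) for name in _SCENARIO_NAMES}


def human_charge_variant(net_charge: float, dose_mg_per_kg: float = 1.0):
    """(params, schedule) for a human IgG charge variant with NSB active.

    Used for the clearance-vs-charge sweep: the human configuration with a
    non-specific 148 kDa IgG whose charge-sensitive parameters resolve from
    the fitted charge relations.
    """
    base = load_scenario("human_anti_tnfa")
    ab = base.antibody.with_overrides(name=f"IgG_z{net_charge:+g}", net_charge=net_charge,
                                      kon=0.0, koff=0.0, keon=0.0, keoff=0.0)
    phys = load_species("human")
    params = build_model_params(phys, ab, None, overrides={"R_m_total": 71.86})
    schedule = DoseSchedule.from_mg_per_kg(dose_mg_per_kg, phys.body_weight_kg, ab.MW_Da)
    return params, schedule
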