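"""Configuration file loading/saving and observation CSV I/O.

Schema (YAML or JSON), all units fixed by the schema — no inference:

.. code-block:: yaml

    patient:
      V_pl0: 2.4          # L
      V_ex0: 12.9         # L
      V_ic: 25.9          # L
      hematocrit: 0.37
    albumin:
      plasma_concentration_0: 4.0   # g/dL
      molecular_weight: 66500.0     # g/mol
      plasma_mass_fraction: 0.40
    toxins:
      - name: IS
        molecular_weight: 213.21    # g/mol, optional (defaults table)
        binding_degree_0: 0.93
        c_total_0: 15.1             # mg/L
        G: 0.0285                   # mg/min
        K_ip_T: 1210.0              # mL/min
        K_ic_T: 103.0               # mL/min
        k1: 3.6e7                   # M^-1 min^-1
    dialyzer:
      preset: F180NR                # or explicit N/L/r_f/t_f/D_h
      KoA: 600.0                    # mL/min
    session:
      duration: 240.0               # min
      Q_b: 300.0                    # mL/min
      Q_d: 700.0                    # mL/min
      UF_volume: 2.0                # L
      mode: in_vivo
      n_x: 100

Observation CSV columns: time_min, toxin, c_total_mg_per_L.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .binding import BindingParameters, association_constant_for_species
from .dialyzer import DIALYZER_PRESETS, DialyzerGeometry
from .patient import PatientState, ToxinParameters, initialize_equilibrium_state
from .simulator import SessionConfig
from .species import DEFAULT_MOLECULAR_WEIGHTS, AlbuminModel, Species
from .units import InvalidParameterError


@dataclass
class ToxinConfig:
    name: str
    binding_degree_0: float
    c_total_0: float
    G: float
    K_ip_T: float
    K_ic_T: float
    k1: float
    molecular_weight: float | None = None

    def species(self) -> Species:
        mw = self.molecular_weight
        if mw is None:
            mw = DEFAULT_MOLECULAR_WEIGHTS[self.name]
        return Species(name=self.name, molecular_weight=mw,
                       binding_degree_0=self.binding_degree_0,
                       c_total_0=self.c_total_0)

    def parameters(self, albumin: AlbuminModel) -> ToxinParameters:
        sp = self.species()
        K_A = association_constant_for_species(sp, albumin)
        binding = (BindingParameters.from_k1_KA(self.k1, K_A)
                   if K_A > 0 else None)
        return ToxinParameters(G=self.G, K_ip_T=self.K_ip_T,
                               K_ic_T=self.K_ic_T, binding=binding)


@dataclass
class RunConfiguration:
    """Complete description of a simulation run."""

    V_pl0: float
    V_ex0: float
    V_ic: float
    hematocrit: float
    albumin: AlbuminModel
    toxins: list[ToxinConfig]
    dialyzer: DialyzerGeometry
    dialyzer_preset: str | None
    session: SessionConfig

    @property
    def volumes(self) -> tuple[float, float, float]:
        """(V_pl0, V_is0, V_ic) with V_is0 = V_ex0 - V_pl0."""
        return self.V_pl0, self.V_ex0 - self.V_pl0, self.V_ic

    def initial_state(self, toxin_name: str) -> PatientState:
        tc = self._toxin(toxin_name)
        return initialize_equilibrium_state(tc.species(), self.albumin,
                                            self.volumes)

    def _toxin(self, name: str) -> ToxinConfig:
        for tc in self.toxins:
            if tc.name == name:
                return tc
        raise KeyError(f"toxin {name!r} not in configuration")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "patient": {"V_pl0": self.V_pl0, "V_ex0": self.V_ex0,
                        "V_ic": self.V_ic, "hematocrit": self.hematocrit},
            "albumin": asdict(self.albumin),
            "toxins": [ {k: v for k, v in asdict(t).items() if v is not None}
                        for t in self.toxins],
            "session": asdict(self.session),
        }
        if self.dialyzer_preset is not None:
            d["dialyzer"] = {"preset": self.dialyzer_preset,
                             "KoA": self.dialyzer.KoA}
        else:
            d["dialyzer"] = asdict(self.dialyzer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfiguration":
        try:
            patient = d["patient"]
            dial = dict(d["dialyzer"])
            session = {**d.get("session", {})}
            hematocrit = patient.get("hematocrit", 0.37)
            session.setdefault("hematocrit", hematocrit)
            if "preset" in dial:
                preset = dial.pop("preset")
                geom = DIALYZER_PRESETS[preset]
                if "KoA" in dial:
                    geom = geom.with_koa(dial["KoA"])
            else:
                preset = None
                geom = DialyzerGeometry(**dial)
            return cls(
                V_pl0=patient["V_pl0"], V_ex0=patient["V_ex0"],
                V_ic=patient["V_ic"], hematocrit=hematocrit,
                albumin=AlbuminModel(**d.get("albumin", {})),
                toxins=[ToxinConfig(**t) for t in d.get("toxins", [])],
                dialyzer=geom, dialyzer_preset=preset,
                session=SessionConfig(**session),
            )
        except KeyError as e:
            raise InvalidParameterError(f"configuration missing field: {e}") from e


def load_config(path: str | Path) -> RunConfiguration:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfiguration.from_dict(data)


def save_config(cfg: RunConfiguration, path: str | Path) -> None:
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_observations(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read an observation CSV into per-toxin frames sorted by time."""
    df = pd.read_csv(path)
    required = {"time_min", "toxin", "c_total_mg_per_L"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"observation CSV must have columns {sorted(required)}")
    return {name: g.sort_values("time_min").reset_index(drop=True)
            for name, g in df.groupby("toxin")}


def save_observations(series: dict[str, tuple], path: str | Path) -> None:
    """Write {toxin: (times, concentrations)} to the observation CSV."""
    rows = []
    for name, (t, c) in series.items():
        for ti, ci in zip(t, c):
            rows.append({"time_min": ti, "toxin": name, "c_total_mg_per_L": ci})
    pd.DataFrame(rows).to_csv(path, index=False)
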