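"""Configuration, provenance and tabular I/O for the pipeline stages.

Compound panels are long-format CSV (one row per compound x channel):

    name, eftpc_max_uM, channel, ic50_uM, hill

Calibration ranges and mechanism specifications ship as packaged data files
and can be overridden with user files of the same schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .drug_block import ChannelBlock, CompoundRecord
from .errors import SchemaError
from .mechanisms import MechanismSpec
from .model import SimulationConfig
from .population import PopulationSpec

PANEL_COLUMNS = ("name", "eftpc_max_uM", "channel", "ic50_uM", "hill")


def load_compound_panel(path) -> list[CompoundRecord]:
    """Read and validate a long-format compound panel CSV."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["name", "channel"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate channel {row['channel']!r} for compound "
            f"{row['name']!r}")
    records = []
    for name, group in df.groupby("name", sort=False):
        eftpc = group["eftpc_max_uM"].unique()
        if len(eftpc) != 1:
            raise SchemaError(f"{path}: inconsistent EFTPC_max for {name!r}")
        blocks = []
        for idx, row in group.iterrows():
            if not row["ic50_uM"] > 0 or not row["hill"] > 0:
                raise SchemaError(
                    f"{path} row {idx}: non-positive ic50/hill for {name!r}")
            blocks.append(ChannelBlock(channel=str(row["channel"]),
                                       ic50=float(row["ic50_uM"]),
                                       hill=float(row["hill"])))
        records.append(CompoundRecord(name=str(name),
                                      eftpc_max=float(eftpc[0]),
                                      blocks=tuple(blocks)))
    return records


def write_compound_panel(records, path) -> None:
    rows = [{"name": r.name, "eftpc_max_uM": r.eftpc_max,
             "channel": b.channel, "ic50_uM": b.ic50, "hill": b.hill}
            for r in records for b in r.blocks]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_calibration_ranges(path=None) -> dict:
    """Biomarker acceptance intervals; packaged defaults when path is None."""
    if path is None:
        with resources.files("inosim.data").joinpath(
                "calibration_ranges.json").open() as fh:
            payload = json.load(fh)
    else:
        payload = json.loads(Path(path).read_text())
    ranges = payload["ranges"] if "ranges" in payload else payload
    return {k: tuple(v) for k, v in ranges.items()}


def load_mechanism_config(path=None) -> tuple[list[MechanismSpec], list[dict]]:
    """Mechanism specs and in vitro EC50 effects; packaged defaults when
    path is None."""
    if path is None:
        with resources.files("inosim.data").joinpath(
                "mechanisms.yaml").open() as fh:
            payload = yaml.safe_load(fh)
    else:
        payload = yaml.safe_load(Path(path).read_text())
    specs = [
        MechanismSpec(name=name, params=tuple(entry["params"]),
                      scan_range=tuple(entry["range"]),
                      direction=entry.get("direction", "increase"))
        for name, entry in payload["mechanisms"].items()
    ]
    return specs, list(payload.get("compounds", []))


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable for provenance."""

    backend: str = "surrogate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    fit_method: str = "both"          # median | bayes | both
    mcmc: dict = field(default_factory=dict)
    compounds_path: str | None = None
    mechanisms_path: str | None = None
    calibration_path: str | None = None
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**payload.pop("simulation", {}))
        pop_payload = payload.pop("population", {})
        if "scale_range" in pop_payload:
            pop_payload["scale_range"] = tuple(pop_payload["scale_range"])
        pop = PopulationSpec(**pop_payload)
        return cls(simulation=sim, population=pop, **payload)

    def digest(self) -> str:
        payload = {
            "backend": self.backend,
            "simulation": asdict(self.simulation),
            "population": {**asdict(self.population)},
            "fit_method": self.fit_method,
            "mcmc": self.mcmc,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        import inosim

        return {
            "package_version": getattr(inosim, "__version__", "unknown"),
            "seed": self.seed,
            "backend": self.backend,
            "config_digest": self.digest(),
        }


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
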