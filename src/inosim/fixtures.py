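"""Synthetic compound panels and default configuration fixtures.

The per-channel binding affinities of the reference compound set live in
unpublished supplementary material, so this module generates *synthetic*
panels with documented affinities in their place: one pure blocker per
channel at three potency tiers (IC50 = EFTPC_max x {0.3, 3, 30}), and a
small multichannel panel with hERG-led profiles typical of torsadogenic
screening compounds. The panels exercise every downstream stage; they do
not reproduce any real compound's pharmacology.
"""

from __future__ import annotations

from pathlib import Path

from importlib import resources

from .drug_block import CHANNEL_TO_FIELD, ChannelBlock, CompoundRecord
from .io import write_compound_panel

#: IC50 as a multiple of EFTPC_max for the three potency tiers.
POTENCY_TIERS = (0.3, 3.0, 30.0)

#: EFTPC_max (uM) used for all synthetic pure blockers.
PURE_BLOCKER_EFTPC = 1.0

#: Hill coefficients cycled across channels (deterministic, seed-independent).
_HILLS = (1.0, 0.8, 1.2)


def pure_blocker_panel() -> list[CompoundRecord]:
    """One synthetic single-channel blocker per channel and potency tier."""
    records = []
    for i, channel in enumerate(sorted(CHANNEL_TO_FIELD)):
        hill = _HILLS[i % len(_HILLS)]
        for tier in POTENCY_TIERS:
            records.append(CompoundRecord(
                name=f"pure_{channel}_x{tier:g}",
                eftpc_max=PURE_BLOCKER_EFTPC,
                blocks=(ChannelBlock(channel=channel,
                                     ic50=tier * PURE_BLOCKER_EFTPC,
                                     hill=hill),),
            ))
    return records


def multichannel_panel() -> list[CompoundRecord]:
    """Synthetic multichannel profiles: hERG-led with calcium/sodium
    off-target block at documented affinity ratios."""
    return [
        CompoundRecord(
            name="synth_herg_cal", eftpc_max=0.05,
            blocks=(ChannelBlock("IKr", ic50=0.15, hill=0.9),
                    ChannelBlock("ICaL", ic50=0.8, hill=1.0),
                    ChannelBlock("INa", ic50=12.0, hill=1.1))),
        CompoundRecord(
            name="synth_balanced", eftpc_max=0.2,
            blocks=(ChannelBlock("IKr", ic50=1.0, hill=1.0),
                    ChannelBlock("ICaL", ic50=1.0, hill=1.0),
                    ChannelBlock("INaL", ic50=2.5, hill=1.0))),
        CompoundRecord(
            name="synth_cal_dominant", eftpc_max=0.02,
            blocks=(ChannelBlock("ICaL", ic50=0.02, hill=1.1),
                    ChannelBlock("IKr", ic50=2.0, hill=1.0))),
        CompoundRecord(
            name="synth_weak_pan", eftpc_max=1.0,
            blocks=(ChannelBlock("IKr", ic50=400.0, hill=1.0),
                    ChannelBlock("ICaL", ic50=900.0, hill=1.0),
                    ChannelBlock("INa", ic50=1500.0, hill=1.0),
                    ChannelBlock("INaK", ic50=2000.0, hill=1.0))),
    ]


def generate_fixtures(out_dir, seed: int = 0) -> dict:
    """Write every fixture file the pipeline consumes into ``out_dir``.

    The panels are deterministic; ``seed`` is recorded for provenance and
    reserved for future randomised panel variants.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["pure_blockers"] = out / "pure_blocker_panel.csv"
    write_compound_panel(pure_blocker_panel(), paths["pure_blockers"])

    paths["multichannel"] = out / "multichannel_panel.csv"
    write_compound_panel(multichannel_panel(), paths["multichannel"])

    for filename in ("table2_reference.csv", "calibration_ranges.json",
                     "mechanisms.yaml"):
        target = out / filename
        target.write_text(
            resources.files("inosim.data").joinpath(filename).read_text())
        paths[filename.split(".")[0]] = target

    return {k: str(v) for k, v in paths.items()}
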