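"""On-disk formats: ATD bundles, CSV spectra, FASTA sequences.

An ATD bundle is a directory holding ``manifest.json`` (species label,
formula, oligomer order, charge, ground-truth families when simulated,
instrument fields, seed) plus one ``atd_<voltage>V.csv`` per drift
voltage with header ``time_ms,intensity``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atd import ATDSet, ATDTrace
from .instrument import InstrumentConfig
from .simulate import ProfileSpectrum

__all__ = [
    "write_atd_bundle",
    "read_atd_bundle",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_chains_fasta",
]


def _voltage_filename(v: float) -> str:
    tag = f"{v:g}".replace(".", "p")
    return f"atd_{tag}V.csv"


def write_atd_bundle(atd: ATDSet, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(atd.manifest, indent=2))
    for tr in atd.traces:
        df = pd.DataFrame({"time_ms": tr.times, "intensity": tr.intensities})
        df.to_csv(out / _voltage_filename(tr.voltage), index=False)
    return out


def read_atd_bundle(bundle_dir) -> ATDSet:
    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    inst = manifest["instrument"]
    config = InstrumentConfig(
        drift_length=inst["drift_length_cm"],
        pressure=inst["pressure_torr"],
        temperature=inst["temperature_K"],
        buffer_gas_mass=inst["buffer_gas_mass_u"],
        voltages=tuple(inst["voltages_V"]),
        dead_time_coeff=inst["dead_time_coeff_us"],
        width_inflation=inst["width_inflation"],
        bin_width=inst["bin_width_us"],
    )
    traces = []
    for v in config.voltages:
        df = pd.read_csv(bundle / _voltage_filename(v))
        traces.append(
            ATDTrace(
                pressure=config.pressure,
                voltage=v,
                times=df["time_ms"].to_numpy(),
                intensities=df["intensity"].to_numpy(),
            )
        )
    return ATDSet(traces=traces, mz=manifest["mz_avg"], meta=config, manifest=manifest)


def write_spectrum_csv(spectrum: ProfileSpectrum, path) -> Path:
    path = Path(path)
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )
    return path


def read_spectrum_csv(path) -> ProfileSpectrum:
    df = pd.read_csv(path)
    return ProfileSpectrum(
        mz=df["mz"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
    )


def read_chains_fasta(path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
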