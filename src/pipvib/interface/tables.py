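"""Packaged reference tables for ethylene glycol.

Machine-readable copies of published reference values used by the comparison
utilities and worked examples: relative conformer energetics (MP2/aug-cc-pVTZ,
CCSD(T), and PIP-PES values, cm^-1), harmonic normal-mode frequencies of the
five low-lying conformers (MP2/aug-cc-pVTZ vs weighted-fit PES, cm^-1;
imaginary frequencies stored as negative numbers), and VSCF/VCI energies with
leading expansion coefficients for the global-minimum tG+g- conformer.
Loaders verify file checksums and row/column counts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTables", "load_fixture_tables", "TableChecksumError"]

_CHECKSUMS = {
    "eg_conformer_energies.csv":
        "584643900b39915bdba24f6772c95ed6d38bf4552cd065a6df1cb752765d8ab2",
    "eg_harmonic_frequencies.csv":
        "98dcab5cd8a7d94347a040fb71b7f37be632c5ba333dff5fbe05f9c4e79cb690",
    "eg_vci_states_tgg.csv":
        "11bc14a7bd0863aac263c0608ff19966add695c4261d35f28f69e2b3929084ff",
}

CONFORMERS_TABLE2 = ("tG+g-", "g+G+g-", "g-G+g-", "tTt", "g+Tg-")


class TableChecksumError(RuntimeError):
    pass


@dataclass
class FixtureTables:
    """Validated reference tables.

    ``conformer_energies``: one row per conformer, columns per method.
    ``harmonic_frequencies``: 24 modes x (5 conformers x 2 methods).
    ``vci_states``: per-band VCI energies and top-3 coefficients (tG+g-).
    """

    conformer_energies: pd.DataFrame
    harmonic_frequencies: pd.DataFrame
    vci_states: pd.DataFrame

    def frequency_columns(self, conformer: str):
        """(MP2, PES) frequency arrays for one of the five conformers."""
        mp2 = self.harmonic_frequencies[f"{conformer}_MP2"].to_numpy(float)
        pes = self.harmonic_frequencies[f"{conformer}_PES"].to_numpy(float)
        return mp2, pes

    def vci_fundamentals(self) -> dict:
        """Band label -> lowest-lying dominant-fundamental CI energy (cm^-1).

        For bands listed with several strongly mixed eigenstates the table's
        canonical fundamental is the state whose leading label matches the
        band's own mode; used for zero-order combination estimates.
        """
        out = {}
        for _, row in self.vci_states.iterrows():
            band = f"nu{int(row.band_mode)}"
            if row.label1 == band and band not in out:
                out[band] = float(row.ci_freq)
        # bend fundamentals are unique rows; mixed CH states may not list a
        # leading own-mode label -- fall back to the first row of the band
        for _, row in self.vci_states.iterrows():
            band = f"nu{int(row.band_mode)}"
            out.setdefault(band, float(row.ci_freq))
        return out


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("pipvib.data").joinpath(name)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise TableChecksumError(
            f"{name}: checksum mismatch ({digest[:12]}... != "
            f"{_CHECKSUMS[name][:12]}...)")
    import io
    return pd.read_csv(io.BytesIO(data))


def load_fixture_tables() -> FixtureTables:
    """Load and validate the packaged reference tables."""
    energies = _read_checked("eg_conformer_energies.csv")
    freqs = _read_checked("eg_harmonic_frequencies.csv")
    vci = _read_checked("eg_vci_states_tgg.csv")

    if len(energies) != 10:
        raise ValueError("conformer energy table must have 10 rows")
    if len(freqs) != 24:
        raise ValueError("frequency table must have 24 modes")
    expected_cols = {f"{c}_{m}" for c in CONFORMERS_TABLE2 for m in ("MP2", "PES")}
    if not expected_cols <= set(freqs.columns):
        raise ValueError("frequency table missing conformer columns")
    if len(vci) != 22:
        raise ValueError("VCI state table must have 22 rows")
    return FixtureTables(conformer_energies=energies,
                         harmonic_frequencies=freqs, vci_states=vci)
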