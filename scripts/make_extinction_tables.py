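"""Regenerate the bundled synthetic extinction tables.

Writes one CSV per chromophore (1 nm grid, 600-1100 nm) under
src/optidens/data/extinction/.  The spectra are the package's synthetic
model spectra (see optidens.chromophores.synthetic_extinction); the
filenames and headers mark them as synthetic.
"""

from pathlib import Path

import numpy as np

from optidens.chromophores import (
    CHROMOPHORE_UNITS,
    ExtinctionRecord,
    save_extinction_csv,
    synthetic_extinction,
)

OUT = Path(__file__).resolve().parents[1] / "src" / "optidens" / "data" / "extinction"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    wl = np.arange(600.0, 1100.0 + 0.5, 1.0)
    for name, unit in CHROMOPHORE_UNITS.items():
        rec = ExtinctionRecord(
            chromophore_name=name,
            wavelength_grid=wl,
            epsilon=synthetic_extinction(name, wl),
            provenance=(
                f"synthetic model spectrum (Gaussian/exponential landmark bands), "
                f"units cm^-1 per {unit}; not a measured compilation -- replace "
                f"with measured extinction tables for quantitative work on real data"
            ),
        )
        save_extinction_csv(rec, OUT / f"{name.lower()}_synthetic.csv")
        print(f"wrote {name}")


if __name__ == "__main__":
    main()
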