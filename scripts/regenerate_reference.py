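"""Regenerate derived fields in the packaged reference data.

Currently fills ``l_ref_m`` in ``segment_reference.yaml``: the
equivalent-cylinder length solving m(3V/(pi L) + L^2)/12 = I_flx_ext at
cohort-mean mass, volume and flexion/extension MoI (larger root).  Run
from the repository root:

    python scripts/regenerate_reference.py
"""

from __future__ import annotations

import pathlib
import re
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import yaml

from caninebsp.bsp_reference import equivalent_cylinder_length

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "caninebsp" / "data"


def main() -> None:
    ref_path = DATA / "segment_reference.yaml"
    raw = yaml.safe_load(ref_path.read_text())
    moi = yaml.safe_load((DATA / "segment_moi.yaml").read_text())
    body_mass = raw["study"]["body_mass_mean_kg"]
    text = ref_path.read_text()
    for name, row in raw["segments"].items():
        mass = row["mass_fraction"] * body_mass
        volume = row["volume_cm3"] * 1e-6
        i_flx = moi["segments"][name]["i_flx_ext"] * moi["scale"]
        l_ref = equivalent_cylinder_length(mass, volume, i_flx)
        print(f"{name:14s} l_ref = {l_ref:.4f} m")
        # rewrite only the l_ref_m line inside this segment's block
        block = re.compile(
            rf"(^  {name}:\n(?:    .*\n)*?    l_ref_m: )\S+", re.MULTILINE
        )
        text, n = block.subn(rf"\g<1>{l_ref:.6f}", text)
        if n != 1:
            raise RuntimeError(f"could not update l_ref_m for {name}")
    ref_path.write_text(text)
    print(f"updated {ref_path}")


if __name__ == "__main__":
    main()
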