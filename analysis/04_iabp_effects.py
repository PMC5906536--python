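"""Summarise the pump's energetic and volumetric effects from the grid run:
ATP-reduction ordering across conditions, regurgitant-volume response, and
the PV-loop changes under aortic regurgitation."""

from pathlib import Path

import pandas as pd

from counterpulse.experiments import atp_reduction_by_condition

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "grid_metrics.csv")

    red = atp_reduction_by_condition(table)
    print("per-beat contractile ATP reduction by the pump:")
    print(f"  no regurgitation : {red['none']:.1f}%")
    print(f"  10% mitral leak  : {red['MR']:.1f}%")
    print(f"  10% aortic leak  : {red['AR']:.1f}%")
    order = red["none"] > red["MR"] > red["AR"] > 0
    print(f"  ordering noVR > MR > AR: {order}")

    def cell(cond, sev, on):
        sel = table[(table.condition == cond) & (table.severity == sev)
                    & (table.iabp == on)].iloc[0]
        return sel

    for cond in ("AR", "MR"):
        off, on = cell(cond, 10.0, False), cell(cond, 10.0, True)
        print(f"{cond} 10%: regurgitant volume {off.regurgitant_volume:.1f} -> "
              f"{on.regurgitant_volume:.1f} mL with pump; "
              f"EDV {off.edv:.1f} -> {on.edv:.1f}, "
              f"ESV {off.esv:.1f} -> {on.esv:.1f} mL")


if __name__ == "__main__":
    main()
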