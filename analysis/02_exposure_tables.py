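"""Annual radon-progeny exposures by age group and microenvironment.

Combines the time-activity table with location EECs (home 71.4, school
24.4, public 15.2, outdoor/vehicle 6 Bq/m3).  Expected outcome: totals
between ~450 000 and ~570 000 h Bq/m3 per year, with indoors-at-home
contributing 82-98% depending on age group.
"""

from pathlib import Path

from radonrisk.exposure import table2_patterns
from radonrisk.pipeline import exposure_table_frame, exposure_totals_frame

OUT = Path("results")


def main() -> None:
    patterns = table2_patterns()
    per_location = exposure_table_frame(patterns)
    totals = exposure_totals_frame(patterns)
    OUT.mkdir(exist_ok=True)
    per_location.to_csv(OUT / "exposure_table.csv", index=False)
    totals.to_csv(OUT / "exposure_totals.csv", index=False)
    print(per_location.to_string(index=False))
    print()
    print(totals.to_string(index=False))
    print(
        "\nIndoor exposure dominates every age group; home alone carries "
        f"{totals['pct_home'].min():.1f}-{totals['pct_home'].max():.1f}% of the annual total."
    )


if __name__ == "__main__":
    main()
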