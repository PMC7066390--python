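"""Semi-quantitative BCL2 grading of visually estimated positive fractions.

The grade buckets the percentage of BCL2-positive tumor cells: 0 only
for a slide with no positive cells at all, then 1 (<=25 %), 2 (26-50 %),
3 (51-75 %) and 4 (>75 %).
"""

from lymphoseg import bcl2_score


def main() -> None:
    print("all cells negative      -> score", bcl2_score(0.0, all_negative=True).score)
    for percent in (10.0, 25.0, 40.0, 60.0, 80.0):
        print(f"{percent:5.1f} % positive cells -> score", bcl2_score(percent).score)


if __name__ == "__main__":
    main()
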