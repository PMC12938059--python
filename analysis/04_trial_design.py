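"""Generate the AX and identification trial lists (plus practice blocks).

Emits seedable CSV trial lists with the study's cell structure: 240 AX
trials (6 reps x 10 same + 10 two-step different pairs x 2 vowel blocks)
and 168 identification trials (7 steps x 6 reps x 2 choice orders x 2
vowel blocks), /i/ block first.
"""

import argparse
from pathlib import Path

from nearmerge import design


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/design"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ax = design.build_ax_blocks(args.seed)
    ident = design.build_id_blocks(args.seed)
    ax_practice, id_practice = design.build_practice_blocks(args.seed)
    for name, df in (("trials_ax.csv", ax), ("trials_id.csv", ident),
                     ("practice_ax.csv", ax_practice),
                     ("practice_id.csv", id_practice)):
        df.to_csv(args.out / name, index=False)
    print(f"AX: {len(ax)} trials ({(ax['delta'] == 0).sum()} same, "
          f"{(ax['delta'] == 2).sum()} different)")
    print(f"ID: {len(ident)} trials; per-step counts per vowel:")
    print(ident.groupby(['vowel', 'step']).size().unstack().to_string())
    print(f"practice: {len(ax_practice)} AX + {len(id_practice)} ID trials")


if __name__ == "__main__":
    main()
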