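"""Trial-list generation for the AX discrimination and identification tasks.

Both tasks are blocked by vowel (/i/ block first, then /a/) and shuffled
uniformly within block with a seeded generator; cell counts are therefore
seed-invariant and only presentation order varies.

AX main task, per vowel block: 6 repetitions of 20 pairs -- 10 "same"
(step distance Delta = 0) and 10 "different" (Delta = 2, the five two-step
pairs 0-2 ... 4-6 in both orders) -- giving 120 trials per block and 240 in
total.  Steps are indexed 0..6 from the /n/ endpoint.  Since 7 continuum
steps cannot fill 10 identity pairs evenly, the same-pair set is the seven
identity pairs plus one extra repetition of steps {0, 3, 6} (configurable).

Identification task: 7 tokens x 6 repetitions x 2 left/right choice orders
x 2 vowels = 168 trials; every step appears 12 times per vowel.

Timing metadata (ISI 750 ms, ITI 550 ms, tokens carry 50 ms edge silences)
is attached to every AX trial row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VOWEL_BLOCKS = ("i", "a")  # fixed presentation order
STEPS = tuple(range(7))
ISI_MS = 750
ITI_MS = 550

DIFFERENT_PAIRS = tuple((s, s + 2) for s in range(5))
EXTRA_SAME_STEPS = (0, 3, 6)

# practice series: a 3-step voice-onset-time (/ba/->/pa/) continuum,
# labelled by VOT in ms
PRACTICE_VOT_MS = (13, 47, 87)


def _shuffled(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    order = rng.permutation(len(df))
    out = df.iloc[order].reset_index(drop=True)
    out["position"] = np.arange(len(out))
    return out


def build_ax_blocks(seed: int, reps: int = 6,
                    extra_same_steps: tuple[int, ...] = EXTRA_SAME_STEPS
                    ) -> pd.DataFrame:
    """AX main-task trial list: 240 rows, /i/ block before /a/ block."""
    rng = np.random.default_rng(seed)
    blocks = []
    for vowel in VOWEL_BLOCKS:
        rows = []
        for rep in range(1, reps + 1):
            for s in STEPS:
                rows.append((vowel, rep, s, s))
            for s in extra_same_steps:
                rows.append((vowel, rep, s, s))
            for a, b in DIFFERENT_PAIRS:
                rows.append((vowel, rep, a, b))
                rows.append((vowel, rep, b, a))
        df = pd.DataFrame(rows, columns=["vowel", "rep", "a_step", "x_step"])
        df["delta"] = (df["a_step"] - df["x_step"]).abs()
        df["isi_ms"] = ISI_MS
        df["iti_ms"] = ITI_MS
        blocks.append(_shuffled(df, rng))
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "task", "ax")
    return out


def build_id_blocks(seed: int, reps: int = 6) -> pd.DataFrame:
    """Identification trial list: 168 rows, each step 12x per vowel."""
    rng = np.random.default_rng(seed)
    blocks = []
    for vowel in VOWEL_BLOCKS:
        rows = [(vowel, rep, s, order)
                for rep in range(1, reps + 1)
                for s in STEPS
                for order in ("AB", "BA")]
        df = pd.DataFrame(rows, columns=["vowel", "rep", "step",
                                         "choice_order"])
        df["iti_ms"] = ITI_MS
        blocks.append(_shuffled(df, rng))
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "task", "id")
    return out


def build_practice_blocks(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Practice lists over the VOT series: 16 AX trials and 12 ID trials.

    AX practice: two repetitions of 8 pairs -- 4 same and 4 different,
    covering the AA, BB, AB and BA pair types -- using the series endpoints
    A (13 ms VOT) and B (87 ms VOT).
    """
    rng = np.random.default_rng(seed)
    a, b = PRACTICE_VOT_MS[0], PRACTICE_VOT_MS[-1]
    pair_block = [(a, a), (b, b), (a, a), (b, b),   # 4 same
                  (a, b), (b, a), (a, b), (b, a)]   # 4 different
    rows = [(rep, x, y) for rep in (1, 2) for (x, y) in pair_block]
    ax = pd.DataFrame(rows, columns=["rep", "a_vot_ms", "x_vot_ms"])
    ax["same"] = ax["a_vot_ms"] == ax["x_vot_ms"]
    ax["isi_ms"] = ISI_MS
    ax["iti_ms"] = ITI_MS
    ax = _shuffled(ax, rng)
    ax.insert(0, "task", "ax_practice")

    id_rows = [(rep, vot, order) for rep in (1, 2)
               for vot in PRACTICE_VOT_MS for order in ("AB", "BA")]
    idp = pd.DataFrame(id_rows, columns=["rep", "vot_ms", "choice_order"])
    idp = _shuffled(idp, rng)
    idp.insert(0, "task", "id_practice")
    return ax, idp
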