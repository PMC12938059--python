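"""Build the 7-step /n/->/l/ continua for both vowel contexts.

Morphs the endpoint pair per vowel by STFT magnitude interpolation (nasal
phase reused), splices into the nasal host, peak-normalizes to 0.99 and
scales average intensity to 70 dB re 2e-5.  Emits the 14-token stimulus
set with a manifest (step, alpha, durations, RMS level).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nearmerge import fixtures, morph
from nearmerge.io import write_token
from nearmerge.tokens import db_rms


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/continua"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for vowel in ("i", "a"):
        nasal, lateral = fixtures.make_endpoint_pair(vowel, seed=args.seed)
        continuum = morph.build_continuum(nasal, lateral)
        for step, token in enumerate(continuum.tokens):
            path = args.out / f"cv_{vowel}_{step}.wav"
            write_token(token, path)
            rows.append({
                "vowel": vowel, "step": step, "alpha": token.meta["alpha"],
                "file": path.name,
                "duration_s": round(token.duration, 6),
                "peak": round(float(np.max(np.abs(token.samples))), 4),
                "rms_db": round(db_rms(token.samples), 3)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(args.out / "continuum_manifest.csv", index=False)
    print(f"wrote {len(rows)} morphed tokens (2 vowels x 7 steps)")
    print(manifest.to_string(index=False))


if __name__ == "__main__":
    main()
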