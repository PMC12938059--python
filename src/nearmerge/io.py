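"""File I/O: WAV waveforms, token read/write (WAV + TextGrid), manifests."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .textgrid import read_textgrid, segments_tier, write_textgrid
from .tokens import SegmentedToken

SEGMENTS_TIER = "segments"


def write_wav(path: str | Path, samples: np.ndarray, fs: int) -> None:
    wavfile.write(str(path), fs, np.asarray(samples, np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(str(path))
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, float), int(fs)


def write_token(token: SegmentedToken, wav_path: str | Path,
                textgrid_path: str | Path | None = None) -> None:
    write_wav(wav_path, token.samples, token.fs)
    if textgrid_path is None:
        textgrid_path = Path(wav_path).with_suffix(".TextGrid")
    tier = segments_tier(token.intervals, token.duration, name=SEGMENTS_TIER)
    write_textgrid([tier], str(textgrid_path))


def read_token(wav_path: str | Path,
               textgrid_path: str | Path | None = None,
               meta: dict | None = None) -> SegmentedToken:
    samples, fs = read_wav(wav_path)
    if textgrid_path is None:
        textgrid_path = Path(wav_path).with_suffix(".TextGrid")
    tiers = read_textgrid(str(textgrid_path))
    tier = next((t for t in tiers if t.name == SEGMENTS_TIER), tiers[0])
    return SegmentedToken(samples, fs, list(tier.intervals), meta or {})


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[str | Path], out_path: str | Path) -> pd.DataFrame:
    """Content-hash manifest; paths are stored relative to the manifest."""
    base = Path(out_path).parent
    rows = [{"path": Path(p).relative_to(base).as_posix(),
             "sha256": file_sha256(p)}
            for p in sorted(map(Path, paths), key=str)]
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df


def verify_manifest(manifest_path: str | Path, base_dir: str | Path) -> bool:
    df = pd.read_csv(manifest_path)
    base = Path(base_dir)
    return all(file_sha256(base / row["path"]) == row["sha256"]
               for _, row in df.iterrows())
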