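"""Plain-text dataset layout: writers and readers.

One directory per cohort:

* ``session.json``   — segment layout, sampling rate, probe geometry
* ``subjects.tsv``   — one row per subject
* ``lexicon.tsv``    — word -> category
* ``transcript_<id>.tsv`` — token, onset_s, offset_s, category
* ``prosody_<id>.csv``    — t_s, f0_hz, voiced
* ``od_<id>.csv``         — long format: t_s, channel, wavelength_nm, delta_od
* ``hemo_<id>.csv``       — t_s, channel, hbo_z, hbr_z (preprocessed)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CohortSpec, HemoSeries, InputError,
                        OpticalRecording, ProsodyTrack, TimedTranscript)
from .lexicon import Lexicon, build_default_lexicon
from .synthetic import (generate_cohort, generate_fnirs, generate_prosody,
                        generate_transcript, subjects_frame)


def write_session(spec: CohortSpec, outdir: Path) -> Path:
    sess = spec.session
    payload = {
        "fs_hz": sess.fs_hz,
        "n_channels": sess.n_channels,
        "target_channel": sess.target_channel,
        "wavelengths_nm": list(sess.wavelengths_nm),
        "sd_separation_cm": sess.sd_separation_cm,
        "segments": {k: list(v) for k, v in sess.segments().items()},
    }
    path = outdir / "session.json"
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_session(dirpath: Path) -> dict:
    payload = json.loads((Path(dirpath) / "session.json").read_text())
    payload["segments"] = {k: tuple(v) for k, v in payload["segments"].items()}
    payload["wavelengths_nm"] = tuple(payload["wavelengths_nm"])
    return payload


def write_transcript(tr: TimedTranscript, path: Path) -> None:
    tr.tokens.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_transcript(path: Path, narration_s: float) -> TimedTranscript:
    df = pd.read_csv(path, sep="\t")
    return TimedTranscript(tokens=df, narration_bounds=(0.0, narration_s))


def write_prosody(track: ProsodyTrack, path: Path) -> None:
    pd.DataFrame({
        "t_s": np.round(track.times_s, 4),
        "f0_hz": np.round(track.f0_hz, 3),
        "voiced": track.voiced.astype(int),
    }).to_csv(path, index=False)


def read_prosody(path: Path) -> ProsodyTrack:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    if t.size > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], atol=1e-6):
            raise InputError(f"{path}: non-uniform frame spacing")
        frame_hz = 1.0 / dt[0]
    else:
        frame_hz = 1.0
    return ProsodyTrack(frame_hz=frame_hz, f0_hz=df["f0_hz"].to_numpy(float),
                        voiced=df["voiced"].to_numpy(bool))


def write_od(rec: OpticalRecording, path: Path) -> None:
    n_ch, n_wl, n = rec.od.shape
    t = np.arange(n) / rec.fs_hz
    frames = []
    for ch in range(n_ch):
        for w, lam in enumerate(rec.wavelengths_nm):
            frames.append(pd.DataFrame({
                "t_s": np.round(t, 4),
                "channel": ch,
                "wavelength_nm": lam,
                "delta_od": rec.od[ch, w],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6e")


def read_od(path: Path, session: dict, subject_id: str | None = None
            ) -> OpticalRecording:
    df = pd.read_csv(path)
    wavelengths = tuple(session["wavelengths_nm"])
    channels = np.sort(df["channel"].unique())
    n = df[(df["channel"] == channels[0])
           & (df["wavelength_nm"] == wavelengths[0])].shape[0]
    od = np.empty((channels.size, len(wavelengths), n))
    for ch in channels:
        for w, lam in enumerate(wavelengths):
            sub = df[(df["channel"] == ch) & (df["wavelength_nm"] == lam)]
            if sub.shape[0] != n:
                raise InputError(f"{path}: channel {ch} at {lam} nm has "
                                 f"{sub.shape[0]} samples, expected {n}")
            od[int(ch), w] = sub["delta_od"].to_numpy(float)
    return OpticalRecording(fs_hz=session["fs_hz"], od=od,
                            wavelengths_nm=wavelengths,
                            segments=session["segments"],
                            sd_separation_cm=session["sd_separation_cm"],
                            subject_id=subject_id)


def write_hemo(hemo: HemoSeries, path: Path) -> None:
    t = np.arange(hemo.n_samples) / hemo.fs_hz
    frames = []
    for ch in range(hemo.n_channels):
        frames.append(pd.DataFrame({
            "t_s": np.round(t, 4), "channel": ch,
            "hbo_z": hemo.hbo[ch], "hbr_z": hemo.hbr[ch],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6e")


def read_hemo(path: Path, session: dict, subject_id: str | None = None,
              zscored: bool = True) -> HemoSeries:
    df = pd.read_csv(path)
    channels = np.sort(df["channel"].unique())
    n = df[df["channel"] == channels[0]].shape[0]
    hbo = np.empty((channels.size, n))
    hbr = np.empty((channels.size, n))
    for ch in channels:
        sub = df[df["channel"] == ch]
        hbo[int(ch)] = sub["hbo_z"].to_numpy(float)
        hbr[int(ch)] = sub["hbr_z"].to_numpy(float)
    return HemoSeries(fs_hz=session["fs_hz"], hbo=hbo, hbr=hbr,
                      segments=session["segments"], zscored=zscored,
                      subject_id=subject_id)


def write_dataset(spec: CohortSpec, outdir: str | Path,
                  lexicon: Lexicon | None = None) -> dict:
    """Generate a full synthetic cohort and write every artifact.

    Returns {'subjects': [...], 'files': [paths...]}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = lexicon or build_default_lexicon()
    files = [write_session(spec, outdir)]
    lex_path = outdir / "lexicon.tsv"
    lexicon.to_tsv(lex_path)
    files.append(lex_path)

    subjects = generate_cohort(spec)
    subj_path = outdir / "subjects.tsv"
    subjects_frame(subjects).to_csv(subj_path, sep="\t", index=False,
                                    float_format="%.4f")
    files.append(subj_path)

    for subj in subjects:
        tr = generate_transcript(subj, spec)
        p_tr = outdir / f"transcript_{subj.id}.tsv"
        write_transcript(tr, p_tr)
        pr = generate_prosody(subj, spec)
        p_pr = outdir / f"prosody_{subj.id}.csv"
        write_prosody(pr, p_pr)
        rec = generate_fnirs(subj, tr, spec)
        p_od = outdir / f"od_{subj.id}.csv"
        write_od(rec, p_od)
        files.extend([p_tr, p_pr, p_od])
    return {"subjects": subjects, "files": files}
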