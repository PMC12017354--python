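"""End-to-end orchestration: in-memory analysis and file-based runs.

``analyze_cohort`` drives the whole chain in memory (simulate ->
preprocess -> features -> event-lock -> statistics) and is what the
statistical tests and reproduction scripts use; ``run_pipeline`` is the
file-based equivalent behind the command-line interface, writing every
artifact with a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (CohortSpec, EffectParams, InputError, NoiseParams,
                        SessionLayout, PTSD, TEC)
from .eventlock import (characterize_timecourse, extract_windows,
                        grand_average, group_channel_test)
from .lexicon import Lexicon, build_default_lexicon
from .lexical import language_features, tag_tokens_lexicon
from .montage import channel_region
from .preprocess import preprocess_recording
from .prosody import prosody_features
from .stats import CorrelationResult, auto_compare, gated_correlation
from .synthetic import (generate_cohort, generate_fnirs, generate_prosody,
                        generate_transcript, subjects_frame)
from . import fileio

log = logging.getLogger(__name__)


def _correlation_or_missing(x, y) -> CorrelationResult:
    """Criterion-D correlation, degrading to 'none' when n is too small."""
    try:
        return gated_correlation(x, y)
    except InputError as exc:
        log.warning("capsD correlation unavailable: %s", exc)
        return CorrelationResult("none", float("nan"), float("nan"))


def subject_windows_and_activation(hemo, onsets_abs, target_channel,
                                   window_s: float = 10.0):
    """Per-channel activation vector plus the target-channel window set.

    Activation for every channel is the pooled 10 s window mean minus the
    pooled digit-task mean, matching :func:`eventlock.subject_activation`.
    """
    n_win = int(round(window_s * hemo.fs_hz))
    starts = np.round(np.asarray(sorted(onsets_abs)) * hemo.fs_hz).astype(int)
    starts = starts[starts + n_win <= hemo.n_samples]
    if starts.size == 0:
        return None, None
    sl = starts[:, None] + np.arange(n_win)[None, :]
    windows = hemo.hbo[:, sl]                     # (n_ch, n_ev, n_win)
    digit = np.concatenate([hemo.hbo[:, hemo.segment_slice("digits1")],
                            hemo.hbo[:, hemo.segment_slice("digits2")]],
                           axis=1)
    activation = windows.mean(axis=(1, 2)) - digit.mean(axis=1)
    target_ws = extract_windows(hemo, np.asarray(sorted(onsets_abs)),
                                target_channel, window_s)
    return activation, target_ws


def analyze_cohort(spec: CohortSpec, lexicon: Lexicon | None = None,
                   compare_groups: bool = True) -> dict:
    """Run the full in-memory pipeline on one synthetic cohort."""
    lexicon = lexicon or build_default_lexicon()
    sess = spec.session
    nar0 = sess.rest_s + sess.digits1_s
    subjects = generate_cohort(spec)

    lang_rows, pros_rows, act_rows = [], [], []
    winsets: dict[str, list] = {PTSD: [], TEC: []}
    excluded: list[str] = []
    for subj in subjects:
        transcript = generate_transcript(subj, spec)
        tagged = tag_tokens_lexicon(transcript, lexicon)
        feats = language_features(transcript, lexicon)
        feats.update(subject_id=subj.id, group=subj.group, capsD=subj.capsD)
        lang_rows.append(feats)
        pf = prosody_features(generate_prosody(subj, spec))
        pf.update(subject_id=subj.id, group=subj.group)
        pros_rows.append(pf)

        rec = generate_fnirs(subj, transcript, spec)
        hemo = preprocess_recording(rec)
        onsets_abs = nar0 + tagged.onsets_for("negative")
        activation, ws = subject_windows_and_activation(
            hemo, onsets_abs, sess.target_channel)
        if activation is None:
            log.warning("subject %s has no usable event windows; excluded "
                        "from channel tests", subj.id)
            excluded.append(subj.id)
            continue
        winsets[subj.group].append(ws)
        for ch in range(sess.n_channels):
            if ch in hemo.bad_channels:
                continue
            act_rows.append({"subject_id": subj.id, "group": subj.group,
                             "channel": ch, "activation": activation[ch]})

    language = pd.DataFrame(lang_rows)
    prosody = pd.DataFrame(pros_rows)
    activation_table = pd.DataFrame(act_rows)
    channel_tests = group_channel_test(activation_table)

    profiles = {}
    curves = {}
    for group in (PTSD, TEC):
        curve = grand_average(winsets[group])
        curves[group] = curve
        profiles[group] = characterize_timecourse(curve, sess.fs_hz)

    results = {
        "spec": spec,
        "subjects": subjects_frame(subjects),
        "language": language,
        "prosody": prosody,
        "activation_table": activation_table,
        "channel_tests": channel_tests,
        "grand_curves": curves,
        "profiles": profiles,
        "excluded_subjects": excluded,
    }
    m = language["group"] == PTSD
    results["capsd_correlation"] = _correlation_or_missing(
        language.loc[m, "neg_pct"], language.loc[m, "capsD"])
    if compare_groups:
        results["group_comparisons"] = compare_feature_groups(language,
                                                              prosody)
    return results


def compare_feature_groups(language: pd.DataFrame,
                           prosody: pd.DataFrame) -> pd.DataFrame:
    """Normality-gated group comparisons of the language/prosody features."""
    rows = []
    for df, cols in ((language, ["neg_pct", "pos_pct", "factual_pct",
                                 "honore_r"]),
                     (prosody, ["mean_pitch_hz", "semitone_change",
                                "pause_count"])):
        a = df[df["group"] == PTSD]
        b = df[df["group"] == TEC]
        for col in cols:
            x = a[col].dropna().to_numpy(float)
            y = b[col].dropna().to_numpy(float)
            res = auto_compare(x, y, variable=col)
            rows.append({"variable": col, "test": res.test,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect_size_name": res.effect_size_name,
                         "effect_size": res.effect_size,
                         "mean_ptsd": x.mean(), "mean_tec": y.mean()})
    return pd.DataFrame(rows)


def channel_tests_frame(channel_tests) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in channel_tests])
    df["region"] = [channel_region(c) for c in df["channel"]]
    return df


# --------------------------------------------------------------------------
# file-based run

@dataclass
class RunConfig:
    """Serializable configuration of one file-based pipeline run."""

    outdir: str = "narrafnirs_run"
    seed: int = 0
    n_ptsd: int = 35
    n_tec: int = 37
    precision: int = 3
    session: dict = field(default_factory=dict)   # SessionLayout overrides
    effect: dict = field(default_factory=dict)    # EffectParams overrides
    noise: dict = field(default_factory=dict)     # NoiseParams overrides
    lexicon_path: str | None = None               # None -> packaged lexicon

    def spec(self) -> CohortSpec:
        noise = NoiseParams(**self.noise)
        eff_kwargs = dict(self.effect)
        eff_kwargs["noise"] = noise
        return CohortSpec(n_ptsd=self.n_ptsd, n_tec=self.n_tec,
                          seed=self.seed,
                          effect=EffectParams(**eff_kwargs),
                          session=SessionLayout(**self.session))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> preprocess -> features -> analyze -> report, with manifest.

    Every output file is checksummed into ``manifest.json``.  A stage
    failure is recorded in the manifest (with partial outputs retained)
    and re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.spec()
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    stage = "simulate"
    try:
        data = fileio.write_dataset(spec, outdir)
        subjects = data["subjects"]
        manifest["stages"].append({"stage": stage, "status": "ok",
                                   "n_subjects": len(subjects)})

        stage = "preprocess"
        session = fileio.read_session(outdir)
        hemo_by_subject = {}
        for subj in subjects:
            rec = fileio.read_od(outdir / f"od_{subj.id}.csv", session,
                                 subj.id)
            hemo = preprocess_recording(rec)
            fileio.write_hemo(hemo, outdir / f"hemo_{subj.id}.csv")
            hemo_by_subject[subj.id] = hemo
        manifest["stages"].append({"stage": stage, "status": "ok"})

        stage = "features"
        if config.lexicon_path:
            lex_file = Path(config.lexicon_path)
            if not lex_file.exists():
                raise InputError(f"lexicon not found: {lex_file}")
            lexicon = Lexicon.from_tsv(lex_file)
        else:
            lexicon = build_default_lexicon()
        lang_rows, pros_rows = [], []
        tagged_by_subject = {}
        for subj in subjects:
            tr = fileio.read_transcript(
                outdir / f"transcript_{subj.id}.tsv",
                spec.session.narration_s)
            tagged_by_subject[subj.id] = tag_tokens_lexicon(tr, lexicon)
            feats = language_features(tr, lexicon)
            feats.update(subject_id=subj.id, group=subj.group,
                         capsD=subj.capsD)
            lang_rows.append(feats)
            track = fileio.read_prosody(outdir / f"prosody_{subj.id}.csv")
            pf = prosody_features(track)
            pf.update(subject_id=subj.id, group=subj.group)
            pros_rows.append(pf)
        language = pd.DataFrame(lang_rows)
        prosody = pd.DataFrame(pros_rows)
        language.to_csv(outdir / "language_features.tsv", sep="\t",
                        index=False)
        prosody.to_csv(outdir / "prosody_features.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "status": "ok"})

        stage = "analyze"
        nar0 = spec.session.rest_s + spec.session.digits1_s
        act_rows = []
        winsets = {PTSD: [], TEC: []}
        for subj in subjects:
            hemo = hemo_by_subject[subj.id]
            onsets = nar0 + tagged_by_subject[subj.id].onsets_for("negative")
            activation, ws = subject_windows_and_activation(
                hemo, onsets, spec.session.target_channel)
            if activation is None:
                continue
            winsets[subj.group].append(ws)
            for ch in range(spec.session.n_channels):
                if ch in hemo.bad_channels:
                    continue
                act_rows.append({"subject_id": subj.id, "group": subj.group,
                                 "channel": ch, "activation": activation[ch]})
        activation_table = pd.DataFrame(act_rows)
        activation_table.to_csv(outdir / "activation_table.tsv", sep="\t",
                                index=False)
        tests = group_channel_test(activation_table)
        channel_tests_frame(tests).to_csv(outdir / "channel_tests.tsv",
                                          sep="\t", index=False)
        profiles = {}
        for group in (PTSD, TEC):
            curve = grand_average(winsets[group])
            profiles[group] = characterize_timecourse(
                curve, spec.session.fs_hz).to_dict()
        (outdir / "timecourse_profiles.json").write_text(
            json.dumps(profiles, indent=2))
        comparisons = compare_feature_groups(language, prosody)
        comparisons.to_csv(outdir / "group_comparisons.tsv", sep="\t",
                           index=False)
        manifest["stages"].append({"stage": stage, "status": "ok"})

        stage = "report"
        target = spec.session.target_channel
        trow = next(r for r in tests if r.channel == target)
        m = language["group"] == PTSD
        corr = _correlation_or_missing(language.loc[m, "neg_pct"],
                                       language.loc[m, "capsD"])
        prec = config.precision
        report = {
            "seed": config.seed,
            "n_ptsd": spec.n_ptsd, "n_tec": spec.n_tec,
            "target_channel": target,
            "target_region": channel_region(target),
            "target_q_value": round(trow.q_value, 6),
            "target_cliffs_delta": round(trow.cliffs_delta, prec),
            "activation_mean_ptsd": round(float(
                activation_table.query("group == @PTSD and channel == @target")
                ["activation"].mean()), prec),
            "activation_mean_tec": round(float(
                activation_table.query("group == @TEC and channel == @target")
                ["activation"].mean()), prec),
            "tec_profile": profiles[TEC],
            "ptsd_profile": profiles[PTSD],
            "neg_pct_mean_ptsd": round(float(
                language.loc[m, "neg_pct"].mean()), prec),
            "neg_pct_mean_tec": round(float(
                language.loc[~m, "neg_pct"].mean()), prec),
            "capsd_correlation": {"method": corr.method,
                                  "r": None if np.isnan(corr.r)
                                  else round(corr.r, prec),
                                  "p": None if np.isnan(corr.p_value)
                                  else round(corr.p_value, prec)},
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"].append({"stage": stage, "status": "ok"})
    except Exception as exc:
        manifest["stages"].append({"stage": stage, "status": "failed",
                                   "error": f"{type(exc).__name__}: {exc}"})
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --------------------------------------------------------------------------
# dataset validation

def validate_dataset(dirpath: str | Path) -> dict:
    """Schema and consistency checks on a written dataset directory."""
    dirpath = Path(dirpath)
    violations: list[str] = []
    checked = 0
    if not dirpath.is_dir():
        return {"violations": [f"{dirpath}: not a directory"],
                "files_checked": 0}
    try:
        session = fileio.read_session(dirpath)
        checked += 1
        segs = session["segments"]
        order = ["rest", "digits1", "narration", "digits2"]
        prev_end = 0.0
        for name in order:
            if name not in segs:
                violations.append(f"session.json: missing segment {name}")
                continue
            a, b = segs[name]
            if abs(a - prev_end) > 1e-6:
                violations.append(
                    f"session.json: segment {name} not contiguous")
            prev_end = b
    except Exception as exc:
        violations.append(f"session.json: unreadable ({exc})")
        session = None

    for path in sorted(dirpath.glob("transcript_*.tsv")):
        checked += 1
        try:
            df = pd.read_csv(path, sep="\t")
            on = df["onset_s"].to_numpy(float)
            bad = np.flatnonzero(np.diff(on) <= 0)
            for i in bad:
                violations.append(
                    f"{path.name}:{i + 2}: onset not strictly increasing")
            if session is not None:
                nar = session["segments"]["narration"]
                dur = nar[1] - nar[0]
                if on.size and (on.min() < 0 or on.max() >= dur):
                    violations.append(f"{path.name}: onsets outside "
                                      f"[0, {dur}) s narration window")
        except Exception as exc:
            violations.append(f"{path.name}: unreadable ({exc})")

    for path in sorted(dirpath.glob("prosody_*.csv")):
        checked += 1
        try:
            fileio.read_prosody(path)
        except Exception as exc:
            violations.append(f"{path.name}: {exc}")

    for path in sorted(dirpath.glob("od_*.csv")):
        checked += 1
        try:
            df = pd.read_csv(path)
            counts = df.groupby(["channel", "wavelength_nm"]).size()
            if counts.nunique() > 1:
                violations.append(
                    f"{path.name}: unequal series lengths across "
                    f"channel/wavelength pairs")
            if session is not None:
                expected = int(round(
                    session["segments"]["digits2"][1] * session["fs_hz"]))
                if counts.iloc[0] != expected:
                    violations.append(
                        f"{path.name}: {counts.iloc[0]} samples per series, "
                        f"expected {expected}")
        except Exception as exc:
            violations.append(f"{path.name}: unreadable ({exc})")

    return {"violations": violations, "files_checked": checked}
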