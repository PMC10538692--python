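"""End-to-end orchestration: audio -> hierarchy -> features -> TE -> stats.

A run is driven by a ``RunConfig`` (fully serializable; the exact config
used is written into the run directory).  Samples are processed in
sample_id order in a single process, so re-running with the same config and
seed reproduces every CSV byte-for-byte.  Per-sample envelope tables are
cached in the run directory and reloaded on resume when their config hash
matches.  In demo mode the synthetic cohort generator stands in for real
recordings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audio, features, pad, stats, synth, te
from .bands import HIERARCHY_BANDS

log = logging.getLogger("amcascade")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, in one serializable object."""

    output_dir: str = "amcascade_run"
    manifest: str | None = None          # CSV manifest of WAV files
    demo: bool = False                   # generate a synthetic cohort instead
    n_per_group: int = 5
    demo_rate_hz: float = 8000.0
    demo_duration_range_s: tuple = (10.0, 30.0)
    demo_overrides: dict = field(default_factory=dict)
    min_duration_s: float = 10.0
    trim_silence: bool = False
    env_grid_hz: float = 160.0
    band_edges_hz: tuple = (1.0, 4.0, 12.0, 40.0)
    allow_nonstandard_bands: bool = False
    recursion: str = "modulator"
    te_rate_hz: float = 120.0
    te_history_L: int = 1
    te_n_bins: int = 4
    te_n_surrogates: int = 19
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    write_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demo_duration_range_s"] = list(self.demo_duration_range_s)
        d["band_edges_hz"] = list(self.band_edges_hz)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "demo_duration_range_s" in raw:
            raw["demo_duration_range_s"] = tuple(raw["demo_duration_range_s"])
        if "band_edges_hz" in raw:
            raw["band_edges_hz"] = tuple(raw["band_edges_hz"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(config: RunConfig) -> list:
    """Schema / band-edge / Nyquist diagnostics.  Never raises."""
    diags = []
    if tuple(config.band_edges_hz) != (1.0, 4.0, 12.0, 40.0):
        if config.allow_nonstandard_bands:
            diags.append(
                f"note: nonstandard band edges {config.band_edges_hz} accepted by override"
            )
        else:
            diags.append(
                f"error: band edges must be 1/4/12/40 Hz (got {config.band_edges_hz}); "
                "set allow_nonstandard_bands to override"
            )
    top_band = config.band_edges_hz[-1]
    if config.te_rate_hz < 2.0 * top_band:
        diags.append(
            f"warning: te_rate_hz={config.te_rate_hz} leaves no Nyquist margin "
            f"for the {config.band_edges_hz[-2]}-{top_band} Hz band"
        )
    if config.env_grid_hz < 4.0 * top_band:
        diags.append(
            f"warning: env_grid_hz={config.env_grid_hz} < 4 x {top_band} Hz "
            "(envelope Nyquist headroom)"
        )
    if not config.demo and config.manifest is None:
        diags.append("error: either a manifest or demo mode is required")
    if config.demo and config.n_per_group < 2:
        diags.append("error: demo mode needs n_per_group >= 2")
    if config.recursion not in ("modulator", "carrier"):
        diags.append(f"error: unknown recursion {config.recursion!r}")
    if not 0 < config.alpha < 1:
        diags.append("error: alpha must lie in (0, 1)")
    return diags


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    """Return (manifest DataFrame with direction labels, list of samples)."""
    if config.demo:
        manifest, synth_samples = synth.generate_cohort(
            config.n_per_group,
            preset_overrides=config.demo_overrides,
            seed=config.seed,
            rate_hz=config.demo_rate_hz,
            duration_range_s=tuple(config.demo_duration_range_s),
            env_grid_hz=config.env_grid_hz,
        )
        return manifest, [s.sample for s in synth_samples]
    mf = audio.read_manifest(config.manifest)
    mf = audio.manifest_with_labels(mf)
    if "speaker_id" not in mf.columns:
        mf["speaker_id"] = np.where(
            mf.role == "respondent", "R_" + mf.dyad_id, "Q_" + mf.dyad_id
        )
    base = Path(config.manifest).parent
    samples = []
    for _, row in mf.iterrows():
        path = Path(row["file"])
        if not path.is_absolute():
            path = base / path
        samples.append(audio.load_sample(path, row))
    return mf, samples


def _envelope_frame(hierarchy: pad.AmHierarchy) -> pd.DataFrame:
    n = hierarchy.bands[0][3].size
    cols = {"time_s": np.arange(n) / hierarchy.env_grid_hz}
    for name, _lo, _hi, env in hierarchy.bands:
        cols[name] = env
    return pd.DataFrame(cols)


def _process_sample(sample, config: RunConfig, env_dir: Path, cfg_hash: str):
    """Cascade + features + TE for one sample, with envelope caching."""
    env_path = env_dir / f"{sample.sample_id}.csv"
    meta_path = env_dir / f"{sample.sample_id}.json"
    hierarchy = None
    if env_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("config_hash") == cfg_hash:
            df = pd.read_csv(env_path)
            bands = [
                (b.name, b.lo_hz, b.hi_hz, df[b.name].to_numpy())
                for b in HIERARCHY_BANDS
            ]
            hierarchy = pad.AmHierarchy(
                bands=bands,
                final_carrier=np.array([]),
                source_sample_id=sample.sample_id,
                env_grid_hz=config.env_grid_hz,
                signal_rate_hz=sample.rate_hz,
                reconstruction_error=meta.get("reconstruction_error", np.nan),
                converged=meta.get("converged", True),
            )
    if hierarchy is None:
        sample = audio.zscore_normalize(sample)
        configs = pad.default_cascade_configs(config.env_grid_hz)
        hierarchy = pad.pad_cascade(sample, configs, recursion=config.recursion)
        _envelope_frame(hierarchy).to_csv(env_path, index=False)
        meta_path.write_text(
            json.dumps(
                {
                    "config_hash": cfg_hash,
                    "reconstruction_error": hierarchy.reconstruction_error,
                    "converged": hierarchy.converged,
                    "duration_s": sample.duration_s,
                },
                indent=2,
            )
        )
    spectra = features.hierarchy_spectra(hierarchy,
                                         min_duration_s=config.min_duration_s)
    powers = features.rhythm_powers(spectra)
    te_results = te.band_pair_te(
        hierarchy,
        te_rate_hz=config.te_rate_hz,
        history_L=config.te_history_L,
        n_bins=config.te_n_bins,
        n_surrogates=config.te_n_surrogates,
        seed=config.seed,
    )
    return hierarchy, spectra, powers, te_results


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all artifacts into the run directory."""
    diags = validate_config(config)
    errors = [d for d in diags if d.startswith("error")]
    for d in diags:
        log.warning(d)
    if errors:
        raise ValueError("; ".join(errors))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    env_dir = out / "envelopes"
    env_dir.mkdir(exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    cfg_hash = config.config_hash()

    manifest, samples = _load_inputs(config)
    if config.trim_silence:
        samples = [audio.trim_silence(s) for s in samples]
    kept = audio.filter_samples(samples, config.min_duration_s)
    log.info("kept %d/%d samples after the %.0f-s duration filter",
             len(kept), len(samples), config.min_duration_s)
    kept = sorted(kept, key=lambda s: s.sample_id)
    manifest = manifest[manifest.sample_id.isin([s.sample_id for s in kept])]
    manifest.to_csv(out / "manifest.csv", index=False)

    power_rows, te_tables, all_spectra = [], [], []
    failures = []
    for sample in kept:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _h, spectra, powers, te_results = _process_sample(
                    sample, config, env_dir, cfg_hash
                )
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            log.error("sample %s failed: %s", sample.sample_id, exc)
            failures.append(sample.sample_id)
            continue
        power_rows.append(
            {"sample_id": sample.sample_id,
             "direction_label": sample.direction_label, **powers}
        )
        te_tables.append(te.te_results_to_tidy(te_results))
        all_spectra.extend(
            s for k, s in spectra.items() if k != "broadband"
        )
    if failures and len(failures) > 0.5 * len(kept):
        raise RuntimeError(
            f"{len(failures)}/{len(kept)} samples failed; aborting run"
        )

    feature_table = stats.build_feature_table(manifest, power_rows, te_tables)
    feature_table.to_csv(out / "features.csv", index=False)
    pd.concat(te_tables, ignore_index=True).to_csv(out / "te.csv", index=False)
    features.spectra_to_tidy(all_spectra).to_csv(out / "spectra.csv", index=False)

    grouping = dict(zip(feature_table.sample_id, feature_table.direction_label))
    delta_spectra = [s for s in all_spectra if s.band_name_of_source == "delta"]
    group_spectra = features.group_average_spectra(delta_spectra, grouping)
    pd.concat(
        [
            pd.DataFrame(
                {"direction_label": label, "freq_hz": s.freqs_hz, "power": s.power,
                 "n": s.n_averaged}
            )
            for label, s in group_spectra.items()
        ],
        ignore_index=True,
    ).to_csv(out / "group_spectra_delta.csv", index=False)

    report = _run_stats(feature_table, config)
    report["n_samples"] = int(feature_table.shape[0])
    report["n_failed"] = len(failures)
    report["failed_samples"] = failures
    report["config_hash"] = cfg_hash
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    rows = []
    for res_list in report["stat_results"].values():
        rows.extend(res_list)
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)

    if config.write_figures:
        _write_figures(out, group_spectra)

    hashes = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*.csv"))
    }
    (out / "output_manifest.json").write_text(json.dumps(hashes, indent=2))
    return out


def _run_stats(feature_table: pd.DataFrame, config: RunConfig) -> dict:
    """Both analysis designs plus the dyadic correlation."""
    te_cols = stats.te_feature_columns()
    a1, a2 = stats.analysis_tables(feature_table)
    out = {"stat_results": {}}
    for name, tbl in (("analysis1_speech", a1), ("analysis2_directed", a2)):
        if tbl.group_label.nunique() < 2:
            continue
        # contrasts run on per-dyad means: samples within a conversational
        # pair are not independent, so dyads are the exchangeable units
        if "dyad_id" in tbl.columns:
            tbl = stats.speaker_average(tbl, unit_col="dyad_id")
            tbl["group_label"] = tbl.direction_label
        res_power = stats.group_contrast(
            tbl, stats.RHYTHM_POWER_COLS,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        res_te = stats.group_contrast(
            tbl, te_cols,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        out["stat_results"][name] = [
            r.to_dict() for r in res_power + res_te
        ]
    # dyadic correlation of prosody power (questioner vs respondent means)
    if {"questioner", "respondent"} <= set(feature_table.get("role", pd.Series())):
        per_dyad = feature_table.pivot_table(
            index="dyad_id", columns="role", values="prosody_power", aggfunc="mean"
        ).dropna()
        if per_dyad.shape[0] >= 4:
            r = stats.dyad_correlation(
                per_dyad["questioner"], per_dyad["respondent"], method="auto"
            )
            out["dyad_correlation_prosody_power"] = r.to_dict()
    return out


def _write_figures(out: Path, group_spectra: dict):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in sorted(group_spectra.items()):
        sel = (s.freqs_hz >= 0.5) & (s.freqs_hz <= 10)
        ax.plot(s.freqs_hz[sel], s.power[sel], label=f"{label} (n={s.n_averaged})")
    ax.set_xlabel("modulation frequency (Hz)")
    ax.set_ylabel("power")
    ax.set_title("Group-mean modulation spectrum, prosodic (delta) envelope")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "group_spectra_delta.png", dpi=120)
    plt.close(fig)
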