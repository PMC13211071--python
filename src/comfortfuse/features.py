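"""Assemble the per-window feature matrix, normalise it, and audit exclusions.

The modelled schema holds exactly 55 features across nine layers. Most
features are z-scored within session — subtracting the session baseline
and dividing by its SD — so models learn deviations from the wearer's
state rather than absolute levels that fingerprint the session. Acoustic
features are the exception and stay absolute: the microphone sits in the
same pocket every session, so the dB level is genuine, comparable acoustic
exposure, and z-scoring would erase the difference between a quiet room
and a noisy one. Magnetometer magnitudes stay z-scored because absolute
field strength varies with location, not comfort.

Candidate features that proxy session or location identity, or reflect
deployment artifacts, are excluded by an explicit audited ledger rather
than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

WITHIN_SESSION_Z = "within_session_z"
ABSOLUTE = "absolute"

#: layer -> ordered feature names; 55 total
LAYERS: dict[str, list[str]] = {
    "hrv_time": ["mean_rr", "sdnn", "rmssd", "sdsd", "pnn50", "mean_hr"],
    "hrv_freq": ["lf_power", "hf_power", "lf_hf_ratio", "total_power"],
    "hrv_nonlinear": ["sd1", "sd2", "sd1_sd2_ratio", "sample_entropy"],
    "hr_wrist": ["hr_mean", "hr_sd", "hr_min", "hr_max", "hr_reserve_mean"],
    "temp": ["temp_mean", "temp_sd", "temp_rate_of_change"],
    "wrist_kinematic": [
        "wrist_accel_mag_mean", "wrist_accel_mag_sd", "wrist_accel_mag_max",
    ],
    "phone_kinematic": [
        "accel_mag_mean", "accel_mag_sd", "accel_mag_min", "accel_mag_max",
        "ax_mean", "ax_sd", "ay_mean", "ay_sd", "az_mean", "az_sd",
        "jerk_mean", "jerk_sd", "jerk_max",
        "gyro_mag_mean", "gyro_mag_sd", "gyro_mag_max",
        "gyro_x_mean", "gyro_x_sd", "gyro_y_mean", "gyro_y_sd",
        "gyro_z_mean", "gyro_z_sd",
    ],
    "acoustic": ["sound_mean", "sound_sd", "sound_min", "sound_max"],
    "magnetic": ["mag_mag_mean", "mag_mag_sd", "mag_mag_min", "mag_mag_max"],
}

N_MODELLED_FEATURES = 55

#: coarse grouping used for interpretability aggregation
REPORT_LAYERS: dict[str, list[str]] = {
    "hrv": ["hrv_time", "hrv_freq", "hrv_nonlinear"],
    "hr_wrist": ["hr_wrist", "temp", "wrist_kinematic"],
    "kinematic": ["phone_kinematic"],
    "acoustic": ["acoustic"],
    "magnetic": ["magnetic"],
}

#: audited exclusion ledger: candidate feature -> reason class
EXCLUSION_LEDGER: dict[str, str] = {
    # varies between locations/sessions, not with comfort within a session
    "altitude_mean": "session_proxy",
    "altitude_rate": "session_proxy",
    "pressure_mean": "session_proxy",
    "pressure_rate": "session_proxy",
    "grav_x_mean": "session_proxy",   # phone orientation in the pocket
    "grav_y_mean": "session_proxy",
    "grav_z_mean": "session_proxy",
    "mag_x_mean": "session_proxy",    # field direction fixed by location/pose
    "mag_y_mean": "session_proxy",
    "mag_z_mean": "session_proxy",
    "is_outdoor": "session_proxy",
    "hour_of_day": "session_proxy",
    # pocket deployment: luxometer measures pocket openness, not ambient light
    "lux_mean": "deployment_artifact",
    "lux_sd": "deployment_artifact",
    # 87.6% missing in the pilot data
    "gps_speed_mean": "missingness",
    "gyro_mag_min": "near_constant",
    # data-quality indicator, not a comfort feature
    "n_beats": "quality_indicator",
    "n_phone_samples": "quality_indicator",
    # direction change captures activity context rather than comfort
    "heading_circ_var": "context_proxy",
}

ID_COLUMNS = ["session_id", "window_index", "window_start_s", "label"]


class SchemaError(Exception):
    """Feature matrix does not match the 55-feature modelled schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered modelled feature names with layer and normalisation tags."""

    names: tuple[str, ...]
    layer_of: dict[str, str]
    normalisation_of: dict[str, str]

    @classmethod
    def default(cls) -> "FeatureSchema":
        names: list[str] = []
        layer_of: dict[str, str] = {}
        norm_of: dict[str, str] = {}
        for layer, feats in LAYERS.items():
            for f in feats:
                names.append(f)
                layer_of[f] = layer
                norm_of[f] = ABSOLUTE if layer == "acoustic" else WITHIN_SESSION_Z
        schema = cls(tuple(names), layer_of, norm_of)
        if len(schema.names) != N_MODELLED_FEATURES:
            raise SchemaError(
                f"schema holds {len(schema.names)} features, expected "
                f"{N_MODELLED_FEATURES}"
            )
        return schema

    def report_layer_of(self, name: str) -> str:
        fine = self.layer_of[name]
        for coarse, members in REPORT_LAYERS.items():
            if fine in members:
                return coarse
        raise SchemaError(f"layer {fine} not mapped to a report layer")

    def fingerprint(self) -> str:
        """Stable digest of ordered names and tags; drift fails tests."""
        payload = [(n, self.layer_of[n], self.normalisation_of[n]) for n in self.names]
        return json.dumps(payload, separators=(",", ":"))


def assemble(
    hrv_rows: dict[tuple[str, int], dict[str, float]],
    context_rows: dict[tuple[str, int], dict[str, float]],
    labels: dict[tuple[str, int], str],
    window_starts: dict[tuple[str, int], float] | None = None,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Join per-window HRV and context rows into the unified feature matrix.

    Rows are keyed by (session_id, window_index); the join is outer, so a
    window that lost one layer (e.g. an HRV window discarded for having
    under 30 beats) keeps the other layer's block and carries missing
    markers for the lost one. Only labelled windows enter the matrix.
    """
    schema = schema or FeatureSchema.default()
    keys = sorted(set(hrv_rows) | set(context_rows))
    records = []
    for key in keys:
        if key not in labels or labels[key] is None:
            continue
        session_id, window_index = key
        row: dict[str, object] = {
            "session_id": session_id,
            "window_index": window_index,
            "window_start_s": (window_starts or {}).get(key, float("nan")),
            "label": labels[key],
        }
        merged: dict[str, float] = {}
        merged.update(hrv_rows.get(key, {}))
        merged.update(context_rows.get(key, {}))
        for name in schema.names:
            row[name] = merged.get(name, float("nan"))
        records.append(row)
    matrix = pd.DataFrame(records, columns=ID_COLUMNS + list(schema.names))
    validate_schema(matrix, schema)
    return matrix


def validate_schema(matrix: pd.DataFrame, schema: FeatureSchema | None = None) -> None:
    schema = schema or FeatureSchema.default()
    feature_cols = [c for c in matrix.columns if c not in ID_COLUMNS]
    if list(feature_cols) != list(schema.names):
        missing = [c for c in schema.names if c not in feature_cols]
        extra = [c for c in feature_cols if c not in schema.names]
        raise SchemaError(
            f"feature columns do not match the {N_MODELLED_FEATURES}-feature "
            f"schema (missing={missing}, unexpected={extra})"
        )


def normalise(
    matrix: pd.DataFrame, schema: FeatureSchema | None = None
) -> pd.DataFrame:
    """Apply the per-layer normalisation policy.

    ``within_session_z`` features are z-scored per session with the n−1
    sample SD (constant columns become 0, not missing, to keep degenerate
    sessions complete; single-window sessions have no baseline and go
    missing). ``absolute`` features pass through unchanged. Idempotent on
    already-normalised columns.
    """
    schema = schema or FeatureSchema.default()
    validate_schema(matrix, schema)
    out = matrix.copy()
    z_cols = [n for n in schema.names if schema.normalisation_of[n] == WITHIN_SESSION_Z]

    def _z(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) < 2:
            return group * float("nan")
        mean = group.mean()
        sd = group.std(ddof=1)
        z = (group - mean) / sd
        constant = sd == 0
        if constant.any():
            z.loc[:, constant.index[constant]] = z.loc[:, constant.index[constant]].fillna(0.0)
        return z

    out[z_cols] = (
        out.groupby("session_id", group_keys=False, sort=False)[z_cols].apply(_z)
    )
    return out


def audit_exclusions(
    candidate_features: list[str], schema: FeatureSchema | None = None
) -> tuple[list[str], dict[str, str]]:
    """Partition candidate features into the modelled schema and the
    exclusion report.

    Every candidate must be either a modelled feature or on the exclusion
    ledger with its reason class; anything unaccounted for raises, so no
    feature can drift into or out of modelling without review.
    """
    schema = schema or FeatureSchema.default()
    modelled: list[str] = []
    report: dict[str, str] = {}
    for name in candidate_features:
        if name in schema.layer_of:
            modelled.append(name)
        elif name in EXCLUSION_LEDGER:
            report[name] = EXCLUSION_LEDGER[name]
        else:
            raise SchemaError(
                f"feature {name!r} is neither modelled nor on the exclusion ledger"
            )
    return modelled, report


def write_matrix(matrix: pd.DataFrame, path, schema: FeatureSchema | None = None) -> None:
    """Persist the matrix as CSV with a sidecar JSON schema."""
    schema = schema or FeatureSchema.default()
    matrix.to_csv(path, index=False)
    sidecar = {
        "features": [
            {
                "name": n,
                "layer": schema.layer_of[n],
                "report_layer": schema.report_layer_of(n),
                "normalisation": schema.normalisation_of[n],
            }
            for n in schema.names
        ],
        "exclusion_ledger": EXCLUSION_LEDGER,
    }
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path)
    validate_schema(matrix)
    return matrix
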