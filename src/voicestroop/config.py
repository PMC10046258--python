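"""Configuration objects for the synthetic cohort and the recognizer model.

All parameters of the generative model live here, as plain dataclasses that
serialize to/from YAML.  Every stochastic stage of the pipeline derives its
random stream deterministically from a single master seed via
``numpy.random.SeedSequence`` spawning, so a config plus its master seed fully
reproduces a cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; message carries the field path."""


@dataclass
class GroupParams:
    """Generative parameters of one participant group.

    Latency model (seconds): a trial in condition c of session j of participant
    i has latency

        mu_c(i) + u_i + s_ij + covariate terms + Normal(0, exg_sigma_s)
               + (Exp(exg_tau_s) - exg_tau_s)

    where ``u_i ~ N(0, sd_between_s)`` is the participant intercept,
    ``s_ij ~ N(0, sd_session_s)`` a session effect, and the centered
    exponential supplies the right-skewed (ex-Gaussian) trial tail while
    keeping ``mu_c`` the full latent condition mean.  Condition means are
    ``mu_neutral_s`` and ``mu_neutral_s + delta_interference_s`` /
    ``mu_neutral_s - delta_facilitation_s`` for incongruent / congruent.
    """

    group: str = "nonpatient"
    mu_neutral_s: float = 0.749
    delta_interference_s: float = 0.113
    delta_facilitation_s: float = 0.047
    sd_between_s: float = 0.075
    sd_session_s: float = 0.040
    exg_sigma_s: float = 0.040
    exg_tau_s: float = 0.050
    dur_mean_s: float = 0.494
    dur_sd_s: float = 0.070
    sd_dur_between_s: float = 0.060
    p_lapse: float = 0.015
    p_wrong_word: float = 0.010
    wer: float = 0.025
    n_sessions: int = 5
    beta_concentration: float = -0.0004
    beta_days: float = 0.0
    beta_days_ama: float = 0.0
    p_ama: float = 0.0
    #: between-participant SDs of the latent effects; 0 pins every participant
    #: to the group deltas exactly
    sd_interference_s: float = 0.0
    sd_facilitation_s: float = 0.0

    def validate(self, path: str = "group") -> None:
        for name in (
            "sd_between_s", "sd_session_s", "exg_sigma_s", "exg_tau_s",
            "dur_sd_s", "sd_dur_between_s", "sd_interference_s", "sd_facilitation_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{path}.{name}: must be >= 0")
        for name in ("p_lapse", "p_wrong_word", "wer", "p_ama"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{path}.{name}: probability must be in [0, 1]")
        if self.n_sessions < 1:
            raise ConfigError(f"{path}.n_sessions: must be >= 1")
        if self.mu_neutral_s <= 0:
            raise ConfigError(f"{path}.mu_neutral_s: must be > 0")


@dataclass
class RecognizerParams:
    """Measurement model of the speech recognizer.

    Detected onsets are the true onsets minus a per-utterance early-detection
    bias ``b ~ N(onset_bias_mean_s, onset_bias_sd_s)``, floor-quantized to the
    recognizer frame grid (default 10 ms).  A fraction ``wer`` of transcripts
    are substituted by a different color word.
    """

    frame_s: float = 0.010
    onset_bias_mean_s: float = 0.036
    onset_bias_sd_s: float = 0.012
    wer: float = 0.0626
    #: "floor" (frame-start indexing) or "nearest"
    rounding: str = "floor"

    def validate(self, path: str = "recognizer") -> None:
        if self.frame_s <= 0:
            raise ConfigError(f"{path}.frame_s: must be > 0")
        if self.onset_bias_sd_s < 0:
            raise ConfigError(f"{path}.onset_bias_sd_s: must be >= 0")
        if not 0.0 <= self.wer <= 1.0:
            raise ConfigError(f"{path}.wer: probability must be in [0, 1]")
        if self.rounding not in ("floor", "nearest"):
            raise ConfigError(f"{path}.rounding: must be 'floor' or 'nearest'")


@dataclass
class CohortConfig:
    """Everything needed to generate and analyze one synthetic two-group cohort."""

    nonpatient: GroupParams = field(default_factory=GroupParams)
    patient: GroupParams = field(
        default_factory=lambda: GroupParams(
            group="patient",
            mu_neutral_s=0.814,
            delta_interference_s=0.112,
            delta_facilitation_s=0.079,
            sd_between_s=0.090,
            sd_session_s=0.045,
            dur_mean_s=0.563,
            dur_sd_s=0.080,
            p_lapse=0.050,
            p_wrong_word=0.035,
            wer=0.0626,
            n_sessions=6,
            beta_days=-0.002,
            beta_days_ama=0.003,
            p_ama=0.30,
        )
    )
    recognizer: RecognizerParams = field(default_factory=RecognizerParams)
    n_nonpatients: int = 113
    n_patients: int = 85
    #: "fixed" = every participant completes group n_sessions;
    #: "poisson" = 1 + Poisson(n_sessions - 1), clipped to [1, 10]
    session_count_dist: str = "fixed"
    icc_k_nonpatient: int = 5
    icc_k_patient: int = 8
    alpha: float = 0.05
    winsorize_z: float = 3.5
    master_seed: int = 20230304

    def validate(self) -> None:
        self.nonpatient.validate("nonpatient")
        self.patient.validate("patient")
        self.recognizer.validate("recognizer")
        if self.n_nonpatients < 0 or self.n_patients < 0:
            raise ConfigError("n_nonpatients/n_patients: must be >= 0")
        if self.n_nonpatients + self.n_patients == 0:
            raise ConfigError("n_nonpatients + n_patients: cohort must be non-empty")
        if self.session_count_dist not in ("fixed", "poisson"):
            raise ConfigError("session_count_dist: must be 'fixed' or 'poisson'")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha: must be in (0, 1)")
        if self.winsorize_z <= 0:
            raise ConfigError("winsorize_z: must be > 0")

    def group_params(self, group: str) -> GroupParams:
        if group == "nonpatient":
            return self.nonpatient
        if group == "patient":
            return self.patient
        raise ConfigError(f"unknown group {group!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        try:
            np_d = d.pop("nonpatient", {})
            pt_d = d.pop("patient", {})
            rec_d = d.pop("recognizer", {})
            cfg = cls(
                nonpatient=GroupParams(**np_d),
                patient=GroupParams(**pt_d),
                recognizer=RecognizerParams(**rec_d),
                **d,
            )
        except TypeError as exc:  # unknown field names
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, stamped into outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def default_config(master_seed: int | None = None) -> CohortConfig:
    cfg = CohortConfig()
    if master_seed is not None:
        cfg.master_seed = int(master_seed)
    cfg.validate()
    return cfg


def save_config(cfg: CohortConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> CohortConfig:
    with open(path) as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))
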