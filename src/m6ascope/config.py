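"""Pipeline configuration: defaults, validation, YAML round trip.

Every numeric parameter of the analysis has a config key.  The defaults are
the published processing parameters: rolling-ball radius 3 px, blur sigma
1.1, 1-px colocalization radius (2 px in antibody-validation mode),
121 x 381 occupancy grid, 31 x 51 density grid, registration outlier
z-score 5, t-SNE perplexity 10.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


@dataclass
class PipelineConfig:
    # grid geometry
    com_shape: tuple[int, int] = (121, 381)
    rdm_shape: tuple[int, int] = (31, 51)
    well_pitch_px: float = 12.0
    # spot detection
    background_radius: int = 3
    smooth_sigma: float = 1.1
    detection_threshold: float | None = None  # None -> median + k*MAD estimate
    threshold_k: float = 5.0
    fit_window: int = 3
    merge_radius: float = 2.0
    # colocalization
    match_radius_px: float = 1.0            # modification calling
    validation_match_radius_px: float = 2.0  # antibody-validation mode
    # registration
    registration_z_threshold: float = 5.0
    # seqFISH / quantification
    round_gene_map: dict[int, str] = field(default_factory=dict)
    housekeeping_genes: tuple[str, ...] = ("GAPDH", "ENO1", "EEF2")
    min_housekeeping_detect: int = 1
    min_gene_total: int = 10
    log_expr_threshold: float = 0.02
    perplexity: float = 10.0
    # phenotype gates: label -> {channel: (lo, hi)}
    phenotype_gates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict)
    # probe design
    gc_bounds: tuple[float, float] = (45.0, 70.0)
    probe_lengths: tuple[int, int] = (25, 30)
    max_homopolymer_run: int = 4
    probe_min_gap: int = 2
    cross_hyb_min_match: int = 17
    readout_max_homology: int = 14
    max_probe_set_size: int = 32
    gc_target: float = 55.0
    # reproducibility
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        return validate_config(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if k in ("com_shape", "rdm_shape", "gc_bounds", "probe_lengths",
                     "housekeeping_genes") and isinstance(v, list):
                v = tuple(v)
            if k == "round_gene_map" and isinstance(v, dict):
                v = {int(r): g for r, g in v.items()}
            if k == "phenotype_gates" and isinstance(v, dict):
                v = {lab: {ch: tuple(b) for ch, b in gate.items()}
                     for lab, gate in v.items()}
            kwargs[k] = v
        return cls(**kwargs).validate()


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Check every invariant; raise ConfigError listing all problems at once."""
    errors: list[str] = []
    if min(cfg.com_shape) <= 0 or min(cfg.rdm_shape) <= 0:
        errors.append("grid shapes must be positive")
    elif not (cfg.rdm_shape[0] < cfg.com_shape[0]
              and cfg.rdm_shape[1] < cfg.com_shape[1]):
        errors.append(
            f"RDM shape {cfg.rdm_shape} must be strictly smaller than COM "
            f"shape {cfg.com_shape} in both dimensions")
    if cfg.background_radius < 1:
        errors.append("background_radius must be >= 1")
    if cfg.smooth_sigma <= 0:
        errors.append("smooth_sigma must be > 0")
    if cfg.detection_threshold is not None and cfg.detection_threshold < 0:
        errors.append("detection_threshold must be >= 0")
    if cfg.match_radius_px <= 0 or cfg.validation_match_radius_px <= 0:
        errors.append("colocalization radii must be > 0")
    if cfg.registration_z_threshold <= 0:
        errors.append("registration_z_threshold must be > 0")
    if cfg.perplexity <= 0:
        errors.append("perplexity must be > 0")
    if cfg.well_pitch_px <= 0:
        errors.append("well_pitch_px must be > 0")
    lo, hi = cfg.gc_bounds
    if not (0 <= lo <= hi <= 100):
        errors.append("gc_bounds must satisfy 0 <= lo <= hi <= 100")
    if cfg.probe_lengths[0] > cfg.probe_lengths[1] or cfg.probe_lengths[0] < 1:
        errors.append("probe_lengths must be an increasing positive range")
    genes_in_map = set(cfg.round_gene_map.values())
    missing_hk = [g for g in cfg.housekeeping_genes if g not in genes_in_map]
    if cfg.round_gene_map and missing_hk and cfg.min_housekeeping_detect > 0:
        errors.append(
            f"housekeeping genes {missing_hk} absent from the round->gene "
            "panel (set min_housekeeping_detect to 0 to disable the QC)")
    if errors:
        raise ConfigError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    return cfg
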