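"""Run configuration: every stage threshold in one place, with the
published operating values as defaults."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # ORF recall
    orf_code: str = "mesodinium"
    orf_min_nt: int = 150
    gain_threshold_aa: int = 100

    # similarity search
    evalue_strict: float = 1e-30  # homolog retention
    evalue_loose: float = 1e-4    # candidate pairing for subtraction
    max_hits: int = 6             # top-best-hit retention per query

    # subtraction (prey-reference screen)
    subtract_identity: float = 0.80
    subtract_slack_aa: int = 150

    # family composition
    stage2_min_core: int = 24
    stage2_min_sra: int = 1
    stage2_min_outgroup: int = 4
    max_family_members: int = 200

    # vetting
    vet_rounds: int = 2
    anchors_required: int = 1
    outgroup_k_min: int = 1
    outgroup_k_max: int = 4
    min_coverage_frac: float = 0.50  # drop short sequences before tree building
    stability_tol: float = 0.25
    keep_one_inparalog_set: bool = True

    # supermatrix
    occupancy_min_frac: float = 0.60
    gene_coverage_min_frac: float = 0.80  # strict >
    fast_site_thresholds: tuple = (2.0, 1.0, 0.8)

    # tree engine
    model_name: str = "poisson"
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    p_invariant: float = 0.0
    use_observed_freqs: bool = True  # "+F"
    bootstrap_n: int = 1000

    # topology tests
    rell_n: int = 10000
    au_scales: tuple = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))
    au_n_per_scale: int = 2000

    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fast_site_thresholds"] = list(self.fast_site_thresholds)
        d["au_scales"] = list(self.au_scales)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k in ("fast_site_thresholds", "au_scales"):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
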