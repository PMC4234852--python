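"""Bundled model configurations for the reference experiments.

Single-enzyme presets place the methyltransferase initiation site at the
array centre (position 25 of 50); dual-enzyme presets give the methyl- and
acetyltransferase their own initiation sites at positions 5 and 45 and lower
the initiation rate to 0.01 s⁻¹ so that recruitment, not initiation,
dominates.  Connectivity presets use the equidistant interaction-site
layouts (2, 3, 5 or 10 sites) with all pairs interacting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CONNECTIVITY_LAYOUTS, ConfigurationError, ModelConfig, RateSet

__all__ = ["Preset", "PRESETS", "EXPERIMENTS", "get_preset", "list_presets"]


@dataclass(frozen=True)
class Preset:
    """A named configuration plus the experiment it belongs to.

    ``kind`` selects the end-to-end analysis run by the CLI ``experiment``
    command: ``illustration`` (kymographs + totals), ``characteristics``
    (stationary profile, activation, count distribution, relaxation),
    ``seeding`` (bistability fractions) or ``boundary`` (M−A window
    distributions).
    """

    name: str
    config: ModelConfig
    t_end: float
    reps: int
    kind: str
    description: str
    seed_counts: tuple = ()


def _single(mechanism: str, **rates) -> ModelConfig:
    return ModelConfig(
        n=50,
        mechanism=mechanism,
        enzymes="single_mt",
        initiation_sites={"Mt": 25},
        rates=RateSet.table1("single_mt", **rates),
        initial_state="all_A_empty",
    )


def _dual(mechanism: str, sites: int = 0, **rates) -> ModelConfig:
    return ModelConfig(
        n=50,
        mechanism=mechanism,
        enzymes="dual",
        initiation_sites={"Mt": 5, "At": 45},
        connectivity_sites=CONNECTIVITY_LAYOUTS[sites] if sites else (),
        rates=RateSet.table1("dual", **rates),
        initial_state="all_U_empty",
    )


def _build() -> dict:
    p: dict = {}

    def add(name, config, t_end, reps, kind, description, seed_counts=()):
        p[name] = Preset(name, config, t_end, reps, kind, description, seed_counts)

    add("fig2", _single("diffusion"), 200, 1, "illustration",
        "Single diffusing methyltransferase entering at position 25")
    add("fig3a", _single("diffusion"), 400, 1000, "characteristics",
        "Four characteristics of the diffusion mechanism")
    add("fig3b", _single("recruitment", k_recruitment=2.4), 400, 1000, "characteristics",
        "Four characteristics of modification-induced recruitment")
    add("fig3c", _single("combined", k_recruitment=2.4), 400, 1000, "characteristics",
        "Four characteristics of the combined diffusion + recruitment mechanism")
    add("fig4a", _single("recruitment", k_recruitment=4.8), 400, 1000, "characteristics",
        "Recruitment mechanism at high efficiency (RE = 2)")
    add("fig4b", _single("combined", k_recruitment=0.24), 400, 1000, "characteristics",
        "Combined mechanism at very low recruitment efficiency (RE = 0.1)")
    # Seeding runs use the relaxation parameters (influx at the initiation
    # site ceased): a no-methylation end state is only stationary with
    # k_on = 0; re-enable influx via config.with_rates(k_on=2.4).
    add("fig5", _single("combined", k_recruitment=2.4, k_on=0.0), 400, 400, "seeding",
        "Seeding bistability of the combined mechanism (no initiation influx)",
        seed_counts=(1, 2, 5))
    add("fig6c", _dual("recruitment", k_recruitment=1.2), 500, 4, "illustration",
        "Opposing transferases, recruitment RE = 0.5")
    add("fig6d", _dual("recruitment", k_recruitment=4.8), 500, 4, "illustration",
        "Opposing transferases, recruitment RE = 2: unstable central boundary")
    add("fig6e", _dual("recruitment", k_recruitment=4.8), 710, 450, "boundary",
        "Boundary statistic (total M − total A) of the RE = 2 regime")
    add("fig6f", _dual("combined", k_recruitment=0.48), 500, 4, "illustration",
        "Opposing transferases, combined mechanism RE = 0.2")
    add("fig7c_i", _dual("recruitment", sites=10, k_recruitment=1.2, k_interaction=0.01),
        500, 4, "illustration", "Recruitment RE = 0.5 with 10 interaction sites at 0.01 s^-1")
    add("fig7c_ii", _dual("recruitment", sites=10, k_recruitment=1.2, k_interaction=0.1),
        500, 4, "illustration", "Recruitment RE = 0.5 with 10 interaction sites at 0.1 s^-1")
    add("fig7d_i", _dual("recruitment", sites=5, k_recruitment=4.8, k_interaction=0.1),
        500, 4, "illustration", "Recruitment RE = 2 with 5 interaction sites at 0.1 s^-1")
    add("fig7d_ii", _dual("recruitment", sites=10, k_recruitment=4.8, k_interaction=0.1),
        500, 4, "illustration", "Recruitment RE = 2 with 10 interaction sites at 0.1 s^-1")
    add("fig7e_i", _dual("combined", sites=5, k_recruitment=0.48, k_interaction=0.01),
        500, 4, "illustration", "Combined RE = 0.2 with 5 interaction sites at 0.01 s^-1")
    add("fig7e_ii", _dual("combined", sites=10, k_recruitment=0.48, k_interaction=0.1),
        500, 4, "illustration", "Combined RE = 0.2 with 10 interaction sites at 0.1 s^-1")

    # connectivity grids: mechanism x {0,2,3,5,10} sites x {0.01, 0.1} s^-1
    grids = {
        "figS1": ("diffusion", 0.6),  # k_recruitment unused by diffusion
        "figS2": ("recruitment", 1.2),
        "figS3": ("recruitment", 4.8),
        "figS4": ("combined", 0.24),
        "figS5": ("combined", 0.48),
    }
    for base, (mechanism, k_rec) in grids.items():
        add(base, _dual(mechanism, k_recruitment=k_rec), 500, 4, "illustration",
            f"{mechanism} mechanism, no connectivity")
        for sites in (2, 3, 5, 10):
            for tag, k_int in (("lo", 0.01), ("hi", 0.1)):
                add(
                    f"{base}_{sites}sites_{tag}",
                    _dual(mechanism, sites=sites, k_recruitment=k_rec, k_interaction=k_int),
                    500, 4, "illustration",
                    f"{mechanism} mechanism, {sites} interaction sites at {k_int} s^-1",
                )
    return p


PRESETS: dict = _build()

#: preset names grouped by the experiment they run end to end
EXPERIMENTS = {name: p.kind for name, p in PRESETS.items()}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list:
    return sorted(PRESETS)
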