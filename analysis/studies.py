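"""Shared definitions of the three emulated ring studies.

The real ring-study scores are restricted, so the analyses run on synthetic
counterparts with the same design:

  RS1  60 core-biopsy slides x 32 pathologists, single region per slide, a
       handful of sporadically missing scores (imputed by per-slide means).
  RS2  60 slides x 28 pathologists, three regions scored and averaged per
       slide and reader biases shrunk by reference-image anchoring — the
       protocol changes that raise agreement.
  RS3  100 whole-section slides x 6 pathologists, single region.

Noise levels are fixed stand-ins (the original variance components were
never published); what matters for the analyses is the structure, not the
exact values.
"""

from pathlib import Path

from tilring.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

RING_STUDIES = {
    "RS1": SimulationConfig(
        n_slides=60, n_readers=32,
        sigma_reader=5.0, sigma_region=11.0, n_regions=1, sigma_error=7.0,
        missing_rate=5 / (60 * 32),  # expect ~5 sporadically missing scores
        seed=101, study_label="ring study 1 (synthetic)",
    ),
    "RS2": SimulationConfig(
        n_slides=60, n_readers=28,
        sigma_reader=2.0,  # reference-image anchoring shrinks reader bias
        sigma_region=11.0, n_regions=3,  # three regions scored and averaged
        sigma_error=5.0,
        seed=102, study_label="ring study 2 (synthetic)",
    ),
    "RS3": SimulationConfig(
        n_slides=100, n_readers=6,
        sigma_reader=5.0, sigma_region=11.0, n_regions=1, sigma_error=7.0,
        seed=103, study_label="ring study 3 (synthetic)",
    ),
}

# manually flagged extras on top of the top-10% SD screen, per study
N_EXTRAS = {"RS1": 1, "RS2": 0, "RS3": 3}


def study_csv(name: str) -> Path:
    return RESULTS / f"{name.lower()}_scores.csv"
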