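import numpy as np
import pytest

from satkit.satsim import FamilySimSpec, SimSpec, build_genome, generate_background, shear_reads
from satkit.seqcore import SatFamily, SatLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One 300 kb genome with two satellite families, masked reads included.

    Session-scoped: several modules reuse it for recovery-style checks.
    """
    from satkit.repeat_align import mask_sample

    rng = np.random.default_rng(777)
    mono_a = generate_background(183, 0.5, rng)
    mono_b = generate_background(60, 0.5, rng)
    spec = SimSpec(
        genome_length=300_000,
        families=[
            FamilySimSpec(monomer=mono_a, target_proportion=0.02, divergence=0.05, name="famA"),
            FamilySimSpec(monomer=mono_b, target_proportion=0.01, divergence=0.12, name="famB"),
        ],
        seed=777,
    )
    genome, truth = build_genome(spec)
    reads = shear_reads(genome, 150, 2.0, 778)
    library = SatLibrary(
        [
            SatFamily(name="famA", rank=1, monomer=mono_a),
            SatFamily(name="famB", rank=2, monomer=mono_b),
        ]
    )
    mask = mask_sample(reads, library, sample="sim")
    return {
        "spec": spec,
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "library": library,
        "mask": mask,
    }
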