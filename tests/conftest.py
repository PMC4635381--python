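"""Shared fixtures: small synthetic spectra and published biomarker rows."""

import numpy as np
import pytest

import archaeotype as at

# Published biomarker peptides with their printed predicted masses (Da).
# Sequences are also packaged in data/biomarker_peptides.fasta.
PUBLISHED_MASSES = {
    "M0KI28": ("MVHCPDCETSLETADDIDFVEVDAVTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA", 6143.86),
    "G0HR47": ("MVHCPDCQTSLETADDIEFVEVDAKTGLIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA", 6151.92),
    "EMA34946": ("MVHCPDCQTSLETADDIDFVEVDATTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA", 6144.84),
    "Q5V7R0": ("MPEFRVRKPDGWTTVSFPDEVATISVVGGKVDGQLCLTFTGEREGGTSVVLDRLLPS", 6152.00),
    "YP_137385": ("MVHCPDCETSLETADDIEFVEVDATTGFIKASKRFYTANCAACGVTIGSGVAGAKSNGGAA", 6159.86),
    "M0JP93": ("MVARLYSATLFALYQLTLLLGIMLLPVAMVTEQFGLRLPMDRAVSGLNEAYDQASA", 6148.31),
    "M0JI28": ("MVHCPDCETSLETADDIEFVEVDAVTGFIKASKRFYTANCATCGVTIGSGVAGAKSNGGAA", 6187.91),
    "L0JI54": ("MTPEATPVGREADRASDVVGAVDEIDGRPHLVVADIARDDAWIAMAESAAVAVEDHR", 6025.64),
    "D2RXY3": ("MSTTSPVFCYVCNEEMVLDETLEHHLVYEHKPRELAKQLVAEWEAEELGEAV", 6034.80),
    "YP_003403049": ("MTLEAESVGSVSVTDGDVVAAIDEIGGQPHLVIADIGRDDVWLSMTERDAVSLDEWR", 6127.76),
    "M0BND2": ("MTPEATPVGREADRASDVVAAVDEIDGRPHLVVADIARDDAWIAMAESAAVAVEDHR", 6039.66),
    "Q8PYQ4": (
        "MVGKMADDMVKEQIYTIPLREVRKVPAWKRAGRAVKEVRGFLVRH"
        "MKTEAEQVKLDKTINECLWEKGCEKPPLSIRVRAVKFADGEVQAELAQ", 10679.59),
    "D7DR73": (
        "MEYIYAALLLNSADKEITEDAVKAVLTAAGIEADDARVKALVAALEGVDIAE"
        "AIAKAAAAPVAVAAAAPAAEAPAEEKKEEKKEDTGAAAAAGLGALFG", 9764.07),
    "D7DV66": (
        "MENERIYTIPLRDVTNKVPTTKRAPRAIKKIREYLQKHMKSDNVKLDNSIN"
        "EKVWERSLNKIPARVRVKAVKQDDVVIATLVE", 9740.40),
    "D5E990": (
        "MPIRDAIHTKGNGCIIDFEINPGSSKLVVPSGYNIWRKRVEGKLTESAQKGK"
        "ANDQLIQRLSHIFQINSSSITIVAGAKTTKKSVHLENVYPKTAEDVLEQYL", 11436.11),
}

# Printed (predicted, observed, error %) triples used for error reproduction.
PUBLISHED_ERRORS = {
    "G0HR47": (6151.92, 6148.08, 0.06),
    "D5E990": (11436.11, 11433.53, 0.02),
    "L0JI54": (6025.64, 6030.57, 0.08),
}


def make_peak_list(mzs, intensities=None, snrs=None, **kwargs) -> at.PeakList:
    """Build a PeakList from plain position/intensity sequences."""
    mzs = list(mzs)
    if intensities is None:
        intensities = [100.0] * len(mzs)
    if snrs is None:
        snrs = [10.0] * len(mzs)
    peaks = sorted(
        (at.Peak(mz=float(m), intensity=float(i), snr=float(s))
         for m, i, s in zip(mzs, intensities, snrs)),
        key=lambda p: p.mz,
    )
    return at.PeakList(peaks=tuple(peaks), **kwargs)


def make_reference(mzs, intensities=None, strain_id="ref", frequencies=None
                   ) -> at.ReferenceSpectrum:
    """Build a ReferenceSpectrum from plain sequences."""
    mzs = list(mzs)
    if intensities is None:
        intensities = [100.0] * len(mzs)
    if frequencies is None:
        frequencies = [1.0] * len(mzs)
    peaks = sorted(
        (at.MspPeak(mz=float(m), intensity=float(i), frequency=float(f))
         for m, i, f in zip(mzs, intensities, frequencies)),
        key=lambda p: p.mz,
    )
    return at.ReferenceSpectrum(
        strain_id=strain_id, peaks=tuple(peaks), n_replicates_used=10
    )


@pytest.fixture
def flat_spectrum() -> at.RawSpectrum:
    """A flat zero signal on the default 1 Da grid."""
    mz = np.arange(2000.0, 20001.0)
    return at.RawSpectrum(mz=mz, intensity=np.zeros_like(mz))


@pytest.fixture
def strain_model() -> at.StrainModel:
    return at.make_strain(seed=11, n_peaks=30, strain_id="fixture-strain")


@pytest.fixture
def noiseless_config() -> at.SimulationConfig:
    return at.SimulationConfig(
        noise_sd=0.0, mz_jitter_ppm=0.0, dropout_prob=0.0,
        spurious_peak_rate=0.0, intensity_cv=0.0, seed=3,
    )
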