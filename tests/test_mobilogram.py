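"""EIM extraction, Gaussian deconvolution, charge gating, resolving power."""

import math

import numpy as np
import pytest

from glycomob.mobilogram import (
    EIM,
    ChargeBand,
    MobilityFrame,
    MobilityPeak,
    charge_gate,
    detect_peaks,
    extract_eim,
    read_frame_csv,
    read_frame_mzml,
    relative_areas,
    resolving_power,
)

from conftest import write_minimal_mzml


def _frame_two_species():
    grid = np.linspace(0.6, 1.6, 1001)
    a = 100.0 * np.exp(-0.5 * ((grid - 1.40) / 0.01) ** 2)
    b = 60.0 * np.exp(-0.5 * ((grid - 1.10) / 0.01) ** 2)
    mz = np.concatenate([np.full(grid.size, 895.341),
                         np.full(grid.size, 952.362)])
    mob = np.concatenate([grid, grid])
    inten = np.concatenate([a, b])
    return MobilityFrame(mz, mob, inten)


def test_extract_conserves_intensity():
    frame = _frame_two_species()
    eim = extract_eim(frame, 895.341, 0.05)
    expected = frame.intensity[np.abs(frame.mz - 895.341) <= 0.05].sum()
    assert eim.total_intensity == pytest.approx(expected, rel=1e-12)


def test_extract_window_selectivity():
    frame = _frame_two_species()
    eim = extract_eim(frame, 895.341, 0.05)
    other = extract_eim(frame, 952.362, 0.05)
    total = frame.intensity.sum()
    assert eim.total_intensity + other.total_intensity == pytest.approx(
        total, rel=1e-12
    )


def test_extract_empty_window_flagged():
    frame = _frame_two_species()
    eim = extract_eim(frame, 500.0, 0.05)
    assert eim.empty and eim.total_intensity == 0.0


def test_single_gaussian_noiseless_area():
    x = np.linspace(0.5, 1.5, 1001)
    y = 100.0 * np.exp(-0.5 * ((x - 1.0) / 0.010) ** 2)
    peaks = detect_peaks(EIM(100.0, 0.05, x, y))
    assert len(peaks) == 1
    assert peaks[0].area == pytest.approx(100 * 0.010 * math.sqrt(2 * math.pi),
                                          abs=1e-6)
    assert peaks[0].area == pytest.approx(2.50663, abs=1e-5)


def test_two_gaussians_6sigma_noiseless_recovery():
    x = np.linspace(0.5, 1.5, 2001)
    y = (100.0 * np.exp(-0.5 * ((x - 1.00) / 0.010) ** 2)
         + 33.3333 * np.exp(-0.5 * ((x - 1.06) / 0.010) ** 2))
    peaks = detect_peaks(EIM(100.0, 0.05, x, y))
    assert len(peaks) == 2
    a1 = 100.0 * 0.010 * math.sqrt(2 * math.pi)
    a2 = 33.3333 * 0.010 * math.sqrt(2 * math.pi)
    assert peaks[0].area == pytest.approx(a1, rel=1e-6)
    assert peaks[1].area == pytest.approx(a2, rel=1e-6)
    # 3:1 area ratio
    assert peaks[0].area / peaks[1].area == pytest.approx(3.0, rel=1e-4)


def test_area_recovery_under_one_percent_noise():
    rng = np.random.default_rng(21)
    x = np.linspace(0.5, 1.5, 2001)
    truth = [(100.0, 1.00, 0.010), (25.0, 1.08, 0.010)]
    y = sum(a * np.exp(-0.5 * ((x - mu) / s) ** 2) for a, mu, s in truth)
    y = y * rng.lognormal(0, 0.01, x.size)
    peaks = detect_peaks(EIM(100.0, 0.05, x, y))
    assert len(peaks) == 2
    for peak, (a, mu, s) in zip(peaks, truth):
        assert peak.area == pytest.approx(a * s * math.sqrt(2 * math.pi),
                                          rel=0.05)


def test_relative_areas():
    def mk(area):
        sigma = 0.01
        return MobilityPeak(centroid=1.0, sigma=sigma,
                            amplitude=area / (sigma * math.sqrt(2 * math.pi)))

    two = relative_areas([mk(3.0), mk(1.0)])
    assert [p.relative_area for p in two] == pytest.approx([75.0, 25.0])
    one = relative_areas([mk(5.0)])
    assert one[0].relative_area == pytest.approx(100.0)
    three = relative_areas([mk(2.0), mk(2.0), mk(4.0)])
    assert [p.relative_area for p in three] == pytest.approx([25.0, 25.0, 50.0])
    assert sum(p.relative_area for p in three) == pytest.approx(100.0, abs=1e-9)
    with pytest.raises(ValueError):
        relative_areas([])


def test_charge_gate():
    frame = _frame_two_species()
    bands = [
        ChargeBand(1, lambda m: 0.9, lambda m: 1.6),
        ChargeBand(2, lambda m: 0.0, lambda m: 0.8),
    ]
    gated = charge_gate(frame, bands)
    assert gated[1].intensity.sum() == pytest.approx(frame.intensity.sum(),
                                                     rel=1e-6)
    assert gated[2].intensity.size + gated["unassigned"].intensity.size + \
        gated[1].intensity.size == frame.intensity.size

    overlapping = [
        ChargeBand(1, lambda m: 0.5, lambda m: 1.6),
        ChargeBand(2, lambda m: 0.4, lambda m: 0.9),
    ]
    with pytest.raises(ValueError, match="overlap"):
        charge_gate(frame, overlapping)


def test_charge_gate_recovers_generator_labels():
    """>=99% of points from distinct charge trendlines gate correctly."""
    rng = np.random.default_rng(8)
    n = 2000
    mz1 = rng.uniform(400, 1100, n)
    mob1 = 0.0012 * mz1 + 0.25 + rng.normal(0, 0.01, n)
    mz2 = rng.uniform(700, 1200, n)
    mob2 = 0.0007 * mz2 + 0.12 + rng.normal(0, 0.01, n)
    frame = MobilityFrame(
        np.concatenate([mz1, mz2]),
        np.concatenate([mob1, mob2]),
        np.ones(2 * n),
    )
    bands = [
        ChargeBand(1, lambda m: 0.0012 * m + 0.25 - 0.05,
                   lambda m: 0.0012 * m + 0.25 + 0.05),
        ChargeBand(2, lambda m: 0.0007 * m + 0.12 - 0.05,
                   lambda m: min(0.0007 * m + 0.12 + 0.05,
                                 0.0012 * m + 0.25 - 0.051)),
    ]
    gated = charge_gate(frame, bands)
    correct = gated[1].mz.size + gated[2].mz.size
    assert correct / (2 * n) >= 0.99


def test_resolving_power():
    peak = MobilityPeak(centroid=1.4, sigma=0.003, amplitude=10.0,
                        ccs=290.0, sigma_ccs=1.0)
    assert resolving_power(peak) == pytest.approx(290 / 2.3548, abs=0.05)
    scaled = MobilityPeak(centroid=1.4, sigma=0.003, amplitude=10.0,
                          ccs=2 * 290.0, sigma_ccs=2.0)
    assert resolving_power(scaled) == pytest.approx(resolving_power(peak))
    degenerate = MobilityPeak(centroid=1.4, sigma=0.003, amplitude=10.0,
                              ccs=290.0, sigma_ccs=0.0)
    assert math.isinf(resolving_power(degenerate))


def test_frame_csv_round_trip(tmp_path):
    path = tmp_path / "frame.csv"
    path.write_text(
        "mz,mobility,intensity\n895.341,1.40,100\n895.341,1.41,50\n"
    )
    frame = read_frame_csv(str(path))
    assert frame.mz.size == 2
    assert frame.intensity.sum() == 150


def test_read_mzml_with_mobility_arrays(tmp_path):
    path = tmp_path / "frame.mzML"
    write_minimal_mzml(path, [895.341, 895.341, 675.247],
                       [1.40, 1.41, 1.10], [100.0, 50.0, 80.0])
    frame = read_frame_mzml(str(path))
    assert frame.mz.size == 3
    assert frame.intensity.sum() == pytest.approx(230.0)
    eim = extract_eim(frame, 895.341, 0.05)
    assert eim.total_intensity == pytest.approx(150.0)
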