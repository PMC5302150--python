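import subprocess

import numpy as np
import pytest
from scipy import integrate, stats

from maraprep.errors import EstimationError, ProcessingError, ValidationError
from maraprep.microarray import (
    BackgroundParams,
    ProbeMatrix,
    adjust_nonspecific,
    background_correct,
    correct_matrix,
    estimate_background,
    expression_mask,
    filter_nonexpressed,
    log_transform,
    process_intensities,
    quantile_normalize,
)
from maraprep.summary import write_summary
from maraprep.synthetic import SimSpec, gen_intensities


def posterior_mean_quadrature(x, p: BackgroundParams) -> float:
    """Numerical integration of E[S | X = x]; the independent oracle."""
    num = integrate.quad(
        lambda s: s * np.exp(-s / p.theta) * stats.norm.pdf(x - s, p.mu, p.sigma),
        0, np.inf)[0]
    den = integrate.quad(
        lambda s: np.exp(-s / p.theta) * stats.norm.pdf(x - s, p.mu, p.sigma),
        0, np.inf)[0]
    return num / den


class TestEstimateBackground:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(42)
        x = rng.normal(100, 15, 50_000) + rng.exponential(200, 50_000)
        p = estimate_background(x)
        assert abs(p.mu - 100) / 100 < 0.10
        assert abs(p.sigma - 15) / 15 < 0.10
        assert abs(p.theta - 200) / 200 < 0.10

    def test_pure_background_degenerates_gracefully(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100, 15, 50_000) + rng.exponential(0.1, 50_000)
        p = estimate_background(x)
        assert abs(p.mu - x.mean()) / x.mean() < 0.05
        assert p.theta < 0.1 * p.mu

    def test_constant_vector_rejected(self):
        with pytest.raises(EstimationError, match="constant"):
            estimate_background(np.full(500, 7.0))

    def test_too_few_probes_rejected(self):
        with pytest.raises(EstimationError, match="100"):
            estimate_background(np.arange(50, dtype=float))


class TestBackgroundCorrect:
    PARAMS = BackgroundParams(100.0, 15.0, 200.0)

    def test_matches_quadrature_oracle(self):
        grid = np.linspace(100 - 3 * 15, 100 + 10 * 15, 25)
        ours = background_correct(grid, self.PARAMS)
        for x, got in zip(grid, ours):
            expected = posterior_mean_quadrature(x, self.PARAMS)
            assert abs(got - expected) / expected < 1e-6

    def test_matches_limma_normexp_signal(self):
        """Independent route: limma's normexp.signal in R."""
        x = [80.0, 100.0, 130.0, 200.0, 400.0, 1000.0]
        script = (
            "suppressMessages(library(limma));"
            f"x <- c({','.join(map(str, x))});"
            "par <- c(100, log(15), log(200));"
            'cat(sprintf("%.8f", normexp.signal(par, x)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        ours = background_correct(np.array(x), self.PARAMS)
        assert np.allclose(ours, reference, rtol=1e-6)

    def test_strictly_increasing_and_positive(self):
        grid = np.linspace(-200, 2000, 4000)
        vals = background_correct(grid, self.PARAMS)
        assert (vals > 0).all()
        assert (np.diff(vals) > 0).all()

    def test_noiseless_limit_subtracts_mu(self):
        p = BackgroundParams(100.0, 1e-4, 200.0)
        assert background_correct(np.array([500.0]), p)[0] == pytest.approx(
            400.0, rel=1e-5)

    def test_deep_left_tail_stays_finite(self):
        vals = background_correct(np.array([-1e4, -1e3]), self.PARAMS)
        assert np.isfinite(vals).all() and (vals > 0).all()


class TestAdjustNonspecific:
    def test_constant_sample_clamps_to_epsilon(self):
        m = ProbeMatrix(["a", "b"], ["s1"], np.full((2, 1), 37.0))
        out = adjust_nonspecific(m, quantile=0.05)
        assert np.allclose(out.values, 1.0)

    def test_within_sample_order_preserved(self):
        rng = np.random.default_rng(3)
        m = ProbeMatrix(
            [f"p{i}" for i in range(300)], ["s1", "s2"],
            rng.exponential(100, (300, 2)) + 5,
        )
        out = adjust_nonspecific(m)
        # monotone shift: sorting by the raw value leaves the adjusted
        # column non-decreasing (the clamp introduces ties, never inversions)
        for j in range(2):
            order = np.argsort(m.values[:, j], kind="stable")
            assert (np.diff(out.values[order, j]) >= 0).all()

    def test_subtracted_floor_is_the_quantile(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(10, 1000, (500, 3))
        m = ProbeMatrix([f"p{i}" for i in range(500)], ["a", "b", "c"], vals)
        out = adjust_nonspecific(m, quantile=0.05)
        floors = np.quantile(vals, 0.05, axis=0)
        expected = np.maximum(vals - floors, 1.0)
        assert np.allclose(out.values, expected)


class TestFilterNonexpressed:
    def _params(self, k):
        return [BackgroundParams(100.0, 15.0, 200.0)] * k

    def test_kept_if_expressed_in_one_sample(self):
        # threshold mu + 2 sigma = 130: probe 'hi' exceeds it in sample 1 only
        corrected = ProbeMatrix(
            ["hi", "lo"], ["s1", "s2", "s3", "s4"],
            np.array([[200.0, 5.0, 5.0, 5.0], [5.0, 5.0, 5.0, 5.0]]),
        )
        keep = expression_mask(corrected, self._params(4))
        assert keep.tolist() == [True, False]

    def test_all_removed_raises(self):
        corrected = ProbeMatrix(["a"], ["s1"], np.array([[5.0]]))
        with pytest.raises(ProcessingError, match="no expressed"):
            filter_nonexpressed(corrected, corrected, self._params(1))

    def test_planted_background_probes_removed(self):
        spec = SimSpec(n_probes=10_000, n_samples=4, frac_background=0.2,
                       seed=19)
        rng = np.random.default_rng(spec.seed + 65537)
        n_bg = 2000
        is_bg = np.zeros(spec.n_probes, dtype=bool)
        is_bg[rng.choice(spec.n_probes, n_bg, replace=False)] = True
        values = rng.normal(spec.mu, spec.sigma, (spec.n_probes, 4))
        signal = rng.exponential(spec.theta, (spec.n_probes, 4))
        signal[is_bg] = 0.0
        values = np.maximum(values + signal, 1e-3)
        m = ProbeMatrix([f"p{i}" for i in range(spec.n_probes)],
                        [f"s{j}" for j in range(4)], values)
        params = [estimate_background(values[:, j]) for j in range(4)]
        corrected = correct_matrix(m, params)
        keep = expression_mask(corrected, params)
        removed_bg = np.mean(~keep[is_bg])
        removed_signal = np.mean(~keep[~is_bg])
        assert removed_bg >= 0.90
        assert removed_signal <= 0.10


class TestQuantileNormalize:
    def _pm(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        return ProbeMatrix(
            ids or [f"p{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])], values,
        )

    def test_hand_worked_example(self):
        out = quantile_normalize(self._pm([[1, 2], [3, 4]]))
        assert np.allclose(out.values, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        col = np.array([[5.0], [2.0], [9.0]])
        m = self._pm(np.hstack([col, col, col]))
        assert np.allclose(quantile_normalize(m).values, m.values)

    def test_columns_share_sorted_vector_and_idempotent(self):
        rng = np.random.default_rng(13)
        m = self._pm(rng.exponential(50, (500, 6)) + 1)
        once = quantile_normalize(m)
        ref = np.sort(once.values[:, 0])
        for j in range(6):
            assert np.allclose(np.sort(once.values[:, j]), ref)
        twice = quantile_normalize(once)
        assert np.allclose(twice.values, once.values)

    def test_ties_get_mean_of_tied_rank_means(self):
        out = quantile_normalize(self._pm([[1, 1], [1, 2], [4, 3]]))
        # col 1 ties at value 1 occupy ranks 0,1 -> both get mean of rank means
        rank_means = np.array([1.0, 1.5, 3.5])
        expected_tied = rank_means[:2].mean()
        assert out.values[0, 0] == out.values[1, 0] == pytest.approx(expected_tied)

    def test_column_means_equalized(self):
        rng = np.random.default_rng(29)
        vals = rng.lognormal(3, 1, (400, 4)) * [1, 2, 5, 10]
        out = quantile_normalize(self._pm(vals))
        means = out.values.mean(axis=0)
        assert np.allclose(means, means[0])

    def test_matches_limma_normalize_quantiles(self, tmp_path):
        rng = np.random.default_rng(31)
        vals = np.round(rng.exponential(100, (20, 4)) + 1, 4)
        m = self._pm(vals)
        path = tmp_path / "m.tsv"
        np.savetxt(path, vals, delimiter="\t", fmt="%.4f")
        script = (
            "suppressMessages(library(limma));"
            f'm <- as.matrix(read.table("{path}", sep="\\t"));'
            'write.table(format(normalizeQuantiles(m), digits=10),'
            ' stdout(), sep="\\t", row.names=FALSE, col.names=FALSE,'
            " quote=FALSE)"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        reference = np.array(
            [[float(v) for v in line.split("\t")]
             for line in out.stdout.strip().splitlines()]
        )
        assert np.allclose(quantile_normalize(m).values, reference, rtol=1e-8)


class TestLogTransformAndChain:
    def test_log2_values(self):
        m = ProbeMatrix(["a", "b"], ["s"], np.array([[1024.0], [1.0]]))
        out = log_transform(m)
        assert out.values[:, 0].tolist() == [10.0, 0.0]

    def test_monotone(self):
        rng = np.random.default_rng(37)
        x = np.sort(rng.uniform(0.5, 1e6, 200))
        m = ProbeMatrix([f"p{i}" for i in range(200)], ["s"], x[:, None])
        assert (np.diff(log_transform(m).values[:, 0]) > 0).all()

    def test_full_chain_deterministic_bytes(self, tmp_path):
        spec = SimSpec(n_probes=2000, n_samples=3, seed=23)
        tsv = tmp_path / "intensities.tsv"
        gen_intensities(spec, tsv)
        from maraprep.microarray import read_intensities

        matrix = read_intensities(tsv)
        paths = []
        for k in range(2):
            summary = process_intensities(matrix)
            p = tmp_path / f"out{k}.tsv"
            write_summary(summary, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


def test_probe_matrix_invariants():
    with pytest.raises(ValidationError):
        ProbeMatrix(["a", "a"], ["s"], np.ones((2, 1)))
    with pytest.raises(ValidationError):
        ProbeMatrix(["a"], ["s"], np.array([[-1.0]]))
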