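"""Sampling-point placement, schedules and the detection overlay."""

import numpy as np
import pytest
from scipy import stats

import pestspread as ps
from pestspread.surveillance import SchemeError


def shared_trial(seed):
    """Uniform variates keyed by (visit month, pixel): couples overlays
    that share sampling pixels and months, for dominance checks."""
    def trial(t, xs, ys):
        return np.array([
            np.random.Generator(np.random.PCG64(
                np.random.SeedSequence((seed, t, int(x), int(y))))).random()
            for x, y in zip(xs, ys)])
    return trial


class TestPoints:
    def test_grid_density4_is_quarter_cell_centres(self, default_landscape):
        xs, ys = ps.generate_points("grid", 4, default_landscape)
        assert len(xs) == 100
        land = default_landscape
        per_field = np.bincount(land.field_id[xs, ys], minlength=26)[1:]
        assert (per_field == 4).all()
        # lower-left field: quarter-cell centres at ±25 m from the corner
        x0, y0, *_ = land.field_bounds(0, 0)
        in_f1 = land.field_id[xs, ys] == 1
        got = sorted(zip(xs[in_f1] - int(x0), ys[in_f1] - int(y0)))
        assert got == [(25, 25), (25, 75), (75, 25), (75, 75)]

    def test_grid_half_density_alternates_checkerboard(self, default_landscape):
        a = ps.generate_points("grid", 0.5, default_landscape, parity=0)
        b = ps.generate_points("grid", 0.5, default_landscape, parity=1)
        assert {len(a[0]), len(b[0])} == {12, 13}
        land = default_landscape
        fa = set(land.field_id[a[0], a[1]])
        fb = set(land.field_id[b[0], b[1]])
        assert fa.isdisjoint(fb)
        assert len(fa | fb) == 25

    def test_random_points_redrawn_and_in_field(self, default_landscape):
        rng = np.random.default_rng(5)
        xs1, ys1 = ps.generate_points("random", 2, default_landscape, rng=rng)
        xs2, ys2 = ps.generate_points("random", 2, default_landscape, rng=rng)
        assert len(xs1) == 50
        land = default_landscape
        assert (np.bincount(land.field_id[xs1, ys1], minlength=26)[1:] == 2).all()
        assert not (np.array_equal(xs1, xs2) and np.array_equal(ys1, ys2))

    def test_strategic_budget_and_interior_coverage(self, default_landscape):
        land = default_landscape
        xs, ys = ps.generate_points("strategic", 4, land)
        assert len(xs) == 100  # same budget as grid at equal density
        per_field = np.bincount(land.field_id[xs, ys], minlength=26)[1:]
        interior_ids = [fy * 5 + fx + 1 for fx in range(1, 4) for fy in range(1, 4)]
        assert all(per_field[i - 1] == 1 for i in interior_ids)
        # every non-interior point hugs the outermost suitable ring
        b0 = 50
        b1 = land.layout.n_pixels - 51
        border_pts = [(x, y) for x, y in zip(xs, ys)
                      if land.field_id[x, y] not in interior_ids]
        assert all(x in (b0, b1) or y in (b0, b1) for x, y in border_pts)

    def test_strategic_budget_too_small_rejected(self):
        land = ps.build_landscape(ps.LandscapeLayout(7, 10, 2, 5, 1))
        with pytest.raises(SchemeError):  # 0.5·49 = 24 < 25 interior fields
            ps.generate_points("strategic", 0.5, land)

    def test_unsupported_inputs_rejected(self, default_landscape):
        with pytest.raises(SchemeError):
            ps.generate_points("grid", 0.3, default_landscape)
        with pytest.raises(SchemeError):
            ps.generate_points("spiral", 1, default_landscape)
        with pytest.raises(SchemeError):
            ps.generate_points("random", 1, default_landscape)  # rng required

    def test_all_arrangements_share_the_total_budget(self, default_landscape):
        rng = np.random.default_rng(6)
        for d in (1, 2, 4, 9, 16, 25):
            ns = {a: len(ps.generate_points(a, d, default_landscape, rng=rng)[0])
                  for a in ps.ARRANGEMENTS}
            assert len(set(ns.values())) == 1


class TestSchedule:
    @pytest.mark.parametrize("freq,t_max,expect", [
        (1, 5, [1, 2, 3, 4, 5]),
        (6, 5, [1]),                        # the program starts in month 1
        (12, 400, list(range(1, 398, 12))),  # 34 yearly visits
    ])
    def test_sampling_times(self, freq, t_max, expect):
        assert list(ps.sampling_times(freq, t_max)) == expect


def _origin_record(land, t_max=24, extra=()):
    """Minimal crafted history: origin infested from month 0, plus optional
    (x, y, t) colonizations."""
    ct = np.full_like(land.field_id, -1, dtype=np.int32)
    origin = tuple(land.suitable_coords[0])
    ct[origin] = 0
    for x, y, t in extra:
        ct[x, y] = t
    return ps.SpreadRecord(ct, origin, np.zeros(t_max + 1, np.int64), t_max,
                           ps.preset("Wei"), land)


def _scheme_at(pixels, frequency=1, p_detect=1.0):
    xs = np.array([p[0] for p in pixels])
    ys = np.array([p[1] for p in pixels])
    return ps.SurveillanceScheme("grid", 1, frequency, p_detect, xs, ys)


class TestOverlay:
    def test_certain_detection_at_first_visit(self, small_landscape, rng):
        rec = _origin_record(small_landscape)
        out = ps.overlay_detection(rec, _scheme_at([rec.origin]), rng)
        assert out.detected and out.T == 1
        assert out.max_dist == 0.0 and out.area == 1.0 and out.n_fields == 1
        assert out.escapes == 0

    def test_zero_detection_probability_never_detects(self, small_landscape, rng):
        rec = _origin_record(small_landscape)
        out = ps.overlay_detection(rec, _scheme_at([rec.origin], p_detect=0.0), rng)
        assert not out.detected and out.T == rec.t_max

    def test_uninfested_points_cannot_detect(self, small_landscape, rng):
        land = small_landscape
        rec = _origin_record(land)
        far = tuple(land.suitable_coords[-1])
        out = ps.overlay_detection(rec, _scheme_at([far]), rng)
        assert not out.detected

    def test_detection_time_is_geometric(self, small_landscape):
        """k points infested from month m, monthly visits: T − m + 1 is
        geometric with success probability 1 − (1 − p)^k."""
        land = small_landscape
        m, p, k = 4, 0.3, 3
        pix = [tuple(c) for c in land.suitable_coords[[10, 50, 200]]]
        rec = _origin_record(land, t_max=300,
                             extra=[(x, y, m) for x, y in pix])
        scheme = _scheme_at(pix, p_detect=p)
        master = np.random.default_rng(77)
        ts = np.array([ps.overlay_detection(rec, scheme, master).T
                       for _ in range(3000)])
        geom_p = 1 - (1 - p) ** k
        waits = ts - m + 1
        assert (ts >= m).all()
        # chi-square against the geometric pmf, pooling the far tail
        kmax = 12
        obs = np.bincount(np.minimum(waits, kmax), minlength=kmax + 1)[1:]
        pmf = geom_p * (1 - geom_p) ** (np.arange(1, kmax + 1) - 1)
        pmf[-1] = (1 - geom_p) ** (kmax - 1)
        assert stats.chisquare(obs, pmf * len(waits)).pvalue > 0.001

    def test_detection_dominance_in_p_density_frequency(self, small_landscape, fast_params):
        """With coupled uniforms, raising p_detect, adding points, or
        visiting more often can never delay detection."""
        land = small_landscape
        rng = np.random.default_rng(9)
        rec = ps.simulate_spread(land, ps.preset("Wei"), fast_params, 40, rng,
                                 origin=(16, 16))
        pix_all = [tuple(c) for c in land.suitable_coords[[30, 150, 400, 700]]]
        for seed in range(30):
            trial = shared_trial(seed)
            t_of = lambda sch: ps.overlay_detection(rec, sch, trial=trial).T
            # detection probability
            assert t_of(_scheme_at(pix_all, p_detect=0.9)) <= \
                   t_of(_scheme_at(pix_all, p_detect=0.4)) <= \
                   t_of(_scheme_at(pix_all, p_detect=0.1))
            # density: nested point sets
            assert t_of(_scheme_at(pix_all, p_detect=0.4)) <= \
                   t_of(_scheme_at(pix_all[:2], p_detect=0.4))
            # frequency: visit months nested (f=2 ⊂ f=1)
            assert t_of(_scheme_at(pix_all, p_detect=0.4, frequency=1)) <= \
                   t_of(_scheme_at(pix_all, p_detect=0.4, frequency=2))

    def test_state_metrics_depend_only_on_T(self, small_landscape, fast_params):
        """Reusing one spread history across many schemes: identical
        detection time implies identical state metrics."""
        land = small_landscape
        rng = np.random.default_rng(10)
        rec = ps.simulate_spread(land, ps.preset("Wei"), fast_params, 40, rng,
                                 origin=(16, 16))
        seen = {}
        master = np.random.default_rng(11)
        for d in (1, 4):
            for f in (1, 2, 3):
                for p in (0.25, 0.75, 1.0):
                    sch = ps.build_scheme("grid", d, f, p, land)
                    sch = ps.SurveillanceScheme("grid", d, f, p,
                                                sch.points_x, sch.points_y)
                    o = ps.overlay_detection(rec, sch, master)
                    key = o.T
                    state = (o.max_dist, o.area, o.n_fields, o.escapes)
                    assert seen.setdefault(key, state) == state

    def test_metrics_of_crafted_state(self, small_landscape, rng):
        land = small_landscape
        origin = (10, 10)
        ct = np.full_like(land.field_id, -1, dtype=np.int32)
        ct[10, 10] = 0
        ct[10, 14] = 1   # 4 m away, same field
        esc = np.zeros(6, np.int64)
        esc[1], esc[2] = 2, 3
        rec = ps.SpreadRecord(ct, origin, esc, 5, ps.preset("Wei"), land)
        out = ps.overlay_detection(rec, _scheme_at([(10, 14)], frequency=3), rng)
        # visits at months 1, 4: the satellite pixel is already infested
        assert out.T == 1
        assert out.area == 2.0 and out.max_dist == 4.0 and out.n_fields == 1
        assert out.escapes == 2
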