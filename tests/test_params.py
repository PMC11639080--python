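"""Parameter-file loading: dialect parsing, scaling, round trips."""

import math
import os
from pathlib import Path

import numpy as np
import pytest

from satfold.params import (
    EnergyParameters,
    ParameterFileError,
    load_parameters,
    write_parameters,
    default_parameter_path,
    RT_KCAL,
    TEMPERATURE_K,
)

MATHEWS_DNA = Path(os.environ.get("CONDA_PREFIX", "/opt/conda/envs/bio")) \
    / "share" / "ViennaRNA" / "dna_mathews2004.par"

HEADER = "## RNAfold parameter file v2.0\n"


def _write(tmp_path, text, name="p.par"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoading:
    def test_empty_file_is_a_parse_error(self, tmp_path):
        with pytest.raises(ParameterFileError, match="header"):
            load_parameters(_write(tmp_path, ""))

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParameterFileError, match="not found"):
            load_parameters(tmp_path / "absent.par")

    def test_bad_header(self, tmp_path):
        with pytest.raises(ParameterFileError, match="header"):
            load_parameters(_write(tmp_path, "not a parameter file\n# stack\n"))

    def test_minimal_stack_only_file(self, tmp_path):
        """A file holding only a stack table loads; CG/CG entry -220
        becomes -2.20 kcal/mol and everything unknowable stays forbidden."""
        rows = []
        for r in range(7):
            row = ["INF"] * 7
            if r == 0:
                row[0] = "-220"
            rows.append(" ".join(row))
        p = load_parameters(_write(tmp_path, HEADER + "# stack\n" + "\n".join(rows) + "\n"))
        assert p.stack[1, 1] == pytest.approx(-2.20)
        assert not np.isfinite(p.stack[1, 2])
        assert not np.isfinite(p.hairpin[5])
        # only CG has a finite stack entry -> only CG allowed
        assert list(p.allowed_pairs[1:7]) == [True, False, False, False, False, False]

    def test_truncated_table_names_table_and_line(self, tmp_path):
        text = HEADER + "# stack\n-220 -180\n# hairpin\nINF\n"
        with pytest.raises(ParameterFileError, match="stack.*truncated|truncated.*stack"):
            load_parameters(_write(tmp_path, text))

    def test_dekacal_scaling_and_tables(self, params):
        # bundled file: CG/CG stack is the unified -2.17 kcal/mol value
        assert params.stack[1, 1] == pytest.approx(-2.17)
        assert params.temperature == TEMPERATURE_K
        assert RT_KCAL == pytest.approx(0.61633, abs=5e-6)

    def test_gt_wobble_only_with_finite_entries(self, params, tmp_path):
        # bundled set: GT/TG marked INF -> disallowed
        assert not params.allowed_pairs[3] and not params.allowed_pairs[4]
        assert params.pair_type(3, 4) == 0  # G,T
        # a file granting GT a finite stack energy enables the wobble
        rows = []
        for r in range(7):
            row = ["INF"] * 7
            if r == 2:
                row[2] = "100"
            rows.append(" ".join(row))
        p = load_parameters(_write(tmp_path, HEADER + "# stack\n" + "\n".join(rows) + "\n"))
        assert p.allowed_pairs[3]
        assert p.pair_type(3, 4) == 3


@pytest.fixture(scope="module")
def par_path():
    """The reference DNA parameter file when the image ships it,
    otherwise the bundled set (either way the oracle is a re-scan of
    the same text the loader parsed)."""
    return MATHEWS_DNA if MATHEWS_DNA.exists() else default_parameter_path()


class TestAgainstIndependentTextScan:
    """Line-oriented re-reading of the same file the loader parsed."""

    def _scan_section(self, path, section):
        vals, active = [], False
        for line in Path(path).read_text().splitlines():
            stripped = line.strip()
            if stripped.startswith("# "):
                active = stripped[2:].strip() == section
                continue
            if active:
                # strip /* comments */ crudely
                while "/*" in stripped:
                    a = stripped.index("/*")
                    b = stripped.find("*/", a)
                    stripped = stripped[:a] + (stripped[b + 2:] if b >= 0 else "")
                for tok in stripped.split():
                    vals.append(math.inf if tok == "INF" else int(tok) / 100.0)
        return vals

    def test_stack_table_matches_text_scan(self, par_path):
        p = load_parameters(par_path)
        vals = self._scan_section(par_path, "stack")[:49]
        got = p.stack[1:8, 1:8].ravel()
        assert len(vals) == 49
        for v, g in zip(vals, got):
            assert (math.isinf(v) and math.isinf(g)) or v == pytest.approx(g)

    def test_loop_tables_match_text_scan(self, par_path):
        p = load_parameters(par_path)
        for section, table in (("hairpin", p.hairpin), ("bulge", p.bulge),
                               ("internal", p.interior)):
            vals = self._scan_section(par_path, section)[:31]
            for v, g in zip(vals, table):
                assert (math.isinf(v) and math.isinf(g)) or v == pytest.approx(g)

    def test_misc_and_ml(self, par_path):
        p = load_parameters(par_path)
        misc = self._scan_section(par_path, "Misc")
        assert p.terminal_at == pytest.approx(misc[2])
        ml = self._scan_section(par_path, "ML_params")
        assert (p.ml_unpaired, p.ml_closing, p.ml_branch) == \
            pytest.approx((ml[0], ml[2], ml[4]))


class TestInvariantsAndRoundTrip:
    def test_loop_tables_nonneg_and_monotone_beyond_3(self, params):
        for tab in (params.hairpin, params.bulge, params.interior):
            finite = tab[np.isfinite(tab)]
            assert (finite >= 0).all()
            tail = tab[4:]
            assert (np.diff(tail[np.isfinite(tail)]) >= -1e-12).all()

    def test_write_and_reload_identical(self, params, tmp_path):
        out = tmp_path / "rt.par"
        write_parameters(params, out)
        p2 = load_parameters(out)
        for name in ("stack", "terminal_mismatch", "dangle5", "dangle3",
                     "hairpin", "bulge", "interior"):
            a, b = getattr(params, name), getattr(p2, name)
            mask = np.isfinite(a)
            assert (np.isfinite(b) == mask).all()
            assert np.allclose(a[mask], b[mask])
        assert p2.ml_closing == params.ml_closing
        assert p2.terminal_at == params.terminal_at
        assert p2.gquad_stack_coeff == params.gquad_stack_coeff

    def test_forbidden_pairs_never_reported_pairable(self, params):
        bases = {1: (2, 3), 2: (3, 2), 3: (3, 4), 4: (4, 3), 5: (1, 4), 6: (4, 1)}
        for pt, (b5, b3) in bases.items():
            if params.allowed_pairs[pt]:
                assert params.pair_type(b5, b3) == pt
            else:
                assert params.pair_type(b5, b3) == 0
        # N never pairs with anything
        for b in range(5):
            assert params.pair_type(0, b) == 0
            assert params.pair_type(b, 0) == 0

    def test_wrong_temperature_rejected(self, params):
        with pytest.raises(ValueError, match="310.15"):
            EnergyParameters(
                stack=params.stack, terminal_mismatch=params.terminal_mismatch,
                dangle5=params.dangle5, dangle3=params.dangle3,
                hairpin=params.hairpin, bulge=params.bulge,
                interior=params.interior, temperature=300.0,
            )
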