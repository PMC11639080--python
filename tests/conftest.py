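"""Shared fixtures: parameter sets, random sequence corpora."""

from __future__ import annotations

import random

import pytest

from satfold import load_parameters, default_parameter_path

TOY_PAR = """\
## RNAfold parameter file v2.0

/* toy DNA set: Watson-Crick stacks at -1.50, GC/GC at -3.00,
   flat-ish loop tables; no dangles, mismatches or multiloop terms */

# stack
/*  CG    GC    GT    TG    AT    TA    NN */
  -150  -150   INF   INF  -150  -150   INF
  -150  -300   INF   INF  -150  -150   INF
   INF   INF   INF   INF   INF   INF   INF
   INF   INF   INF   INF   INF   INF   INF
  -150  -150   INF   INF  -150  -150   INF
  -150  -150   INF   INF  -150  -150   INF
   INF   INF   INF   INF   INF   INF   INF

# hairpin
   INF   INF   INF   400   410   420   430   440   450   460
   470   480   490   500   510   520   530   540   550   560
   570   580   590   600   610   620   630   640   650   660
   670

# bulge
   INF   380   390   400   410   420   430   440   450   460
   470   480   490   500   510   520   530   540   550   560
   570   580   590   600   610   620   630   640   650   660
   670

# internal
   INF   INF   350   360   370   380   390   400   410   420
   430   440   450   460   470   480   490   500   510   520
   530   540   550   560   570   580   590   600   610   620
   630
"""


@pytest.fixture(scope="session")
def params():
    """The bundled unified DNA dG37 parameter set."""
    return load_parameters(default_parameter_path())


@pytest.fixture(scope="session")
def toy_params(tmp_path_factory):
    """Minimal stacks-plus-loops fixture set with hand-checkable values."""
    path = tmp_path_factory.mktemp("par") / "toy.par"
    path.write_text(TOY_PAR)
    return load_parameters(path)


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def short_corpus():
    """Seeded random sequences (length 10-18) for oracle comparisons."""
    rng = random.Random(20240501)
    return [random_dna(rng, rng.randint(10, 18)) for _ in range(200)]
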