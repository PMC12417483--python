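import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def complaints_csv(tmp_path):
    """Small complaint table with one blank-text row and one bad date."""
    path = tmp_path / "complaints.csv"
    path.write_text(
        "id,date,channel,text\n"
        "c1,2024-01-05,internal,poor attitude here\n"
        "c2,2024-13-45,external,long wait at counter\n"
        "c3,2024/02/10,internal,room was dirty\n"
        "c4,2024-03-01,external,\n"
        "c5,,internal,helpful and kind staff\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def lexicon_tsv(tmp_path):
    path = tmp_path / "lexicon.tsv"
    path.write_text(
        "# toy lexicon\n"
        "good\t2.0\n"
        "bad\t-3.0\n"
        "dirty\t-2.0\n"
        "helpful\t2.0\n"
        "kind\t3.0\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def stopwords_txt(tmp_path):
    path = tmp_path / "stopwords.txt"
    path.write_text("# comments allowed\nthe\na\nwas\nat\nand\n", encoding="utf-8")
    return path
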