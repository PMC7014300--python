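import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def write_string_file(path, rows, header="protein1 protein2 combined_score"):
    """Write a STRING-dialect links file from (a, b, score) tuples."""
    with open(path, "w") as handle:
        handle.write(header + "\n")
        for a, b, score in rows:
            handle.write(f"{a} {b} {score}\n")
    return path


@pytest.fixture
def string_file(tmp_path):
    def _make(rows, name="links.tsv", header="protein1 protein2 combined_score"):
        return write_string_file(tmp_path / name, rows, header=header)

    return _make


@pytest.fixture
def gmt_file(tmp_path):
    def _make(lines, name="sets.gmt"):
        path = tmp_path / name
        with open(path, "w") as handle:
            for line in lines:
                handle.write("\t".join(line) + "\n")
        return path

    return _make
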