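"""Packaged example data.

The prostate-cancer acid-phosphatase data: serum acid phosphatase for 53
prostate-cancer patients, 20 with confirmed nodal involvement (diseased)
and 33 without (non-diseased).  Nodal involvement is otherwise confirmed
by surgery, so a serum marker cut-off with a high Youden Index would be
clinically valuable.
"""

from importlib import resources

from .estimate import TwoGroupSample
from .io import read_two_group

__all__ = ["load_prostate", "PROSTATE_LABELS"]

PROSTATE_LABELS = ("nodal_neg", "nodal_pos")


def prostate_path():
    """Filesystem path of the packaged prostate CSV (long layout)."""
    return resources.files("youdenci.data").joinpath("prostate.csv")


def load_prostate() -> TwoGroupSample:
    """The prostate acid-phosphatase sample (m=33 non-diseased, n=20 diseased)."""
    with resources.as_file(prostate_path()) as path:
        return read_two_group(path, layout="long", labels=PROSTATE_LABELS)
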