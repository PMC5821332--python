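import pytest

from aimm.rubric import (
    ResponseOption, Rubric, RubricItem, load_canonical_rubric,
)


def make_item(item_id, points, domain="governance", weight=2):
    """Item with one option per point value, ranks 0,1,2,..."""
    return RubricItem(
        item_id=item_id,
        stem=f"stem for {item_id}",
        domain=domain,
        midwife_types=("CNM", "CM", "CPM"),
        importance_weight=weight,
        options=[
            ResponseOption(code=f"o{k}", label=f"option {k}", raw_rank=k,
                           points=float(p))
            for k, p in enumerate(points)
        ],
    )


@pytest.fixture(scope="session")
def canonical_rubric():
    return load_canonical_rubric()


@pytest.fixture
def toy_rubric():
    """3 items with maxima 4 + 2 + 3 = 9."""
    return Rubric(
        version="toy",
        items=[
            make_item("a", [0, 4], domain="scope of practice"),
            make_item("b", [0, 2], domain="autonomy"),
            make_item("c", [0, 1, 3], domain="quality"),
        ],
        target_total=9.0,
    )
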