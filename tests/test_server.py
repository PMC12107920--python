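"""Queue semantics: FIFO dispatch, ACK-first intake, the 3-attempt retry."""

import time

import pytest

from histolink.errors import DeliveryError
from histolink.hl7 import OrderPayload, build_ack, build_oml_o33
from histolink.hl7.profile import ack_code
from histolink.pipeline import run_inference
from histolink.server import (
    AiDssCore,
    AiDssServer,
    AnalysisRequest,
    default_mode_trigger,
)


def aa_sender(message, request):
    return build_ack(message, "AA")


def make_request(model, location="synthetic://slide", tag=""):
    return AnalysisRequest(
        order=OrderPayload(model, model, location, slide_id=tag)
    )


@pytest.fixture(scope="module")
def canned_processor(registry, slide_reader):
    """Processor backed by one precomputed inference per needed model."""
    from histolink.heatmap import build_project

    cache = {}

    def processor(request, spec, delay=0.0):
        if spec.name not in cache:
            bundle = run_inference(slide_reader, spec, seed=1)
            cache[spec.name] = (bundle, build_project(spec, bundle,
                                                      slide_reader.ref))
        if delay:
            time.sleep(delay)
        return cache[spec.name]

    return processor


class TestIntake:
    def test_valid_order_is_acked_aa_and_enqueued(self, registry):
        core = AiDssCore(registry, result_sender=aa_sender)
        wire = build_oml_o33(
            OrderPayload("m", "breast-tumor-resnet34.tcga-brca", "/wsi/a.svs")
        ).to_bytes()
        ack, request = core.handle_order_bytes(wire)
        assert ack_code(ack) == "AA"
        assert request is not None and core.pending == 1

    def test_malformed_bytes_acked_ae_nothing_enqueued(self, registry):
        core = AiDssCore(registry, result_sender=aa_sender)
        ack, request = core.handle_order_bytes(b"this is not HL7 at all")
        assert ack_code(ack) == "AE"
        assert request is None and core.pending == 0

    def test_profile_violation_acked_ar(self, registry):
        core = AiDssCore(registry, result_sender=aa_sender)
        msg = build_oml_o33(OrderPayload("m", "x", "/wsi/a.svs"))
        spm = msg.segment("SPM")
        msg.segments.insert(msg.segments.index(spm), spm)  # two SPM
        ack, request = core.handle_order_bytes(msg.to_bytes())
        assert ack_code(ack) == "AR"
        assert request is None and core.pending == 0


class TestFifoAndRetry:
    def test_completion_order_equals_arrival_order(self, registry,
                                                   canned_processor):
        # scripted latencies: later arrivals are faster, yet FIFO holds
        delays = {"a": 0.05, "b": 0.02, "c": 0.0}

        def processor(request, spec):
            return canned_processor(
                request, spec, delay=delays[request.order.slide_id]
            )

        core = AiDssCore(registry, processor, aa_sender)
        model = "breast-tumor-resnet34.tcga-brca"
        for tag in ("a", "b", "c"):
            core.enqueue(make_request(model, tag=tag))
        core.drain()
        finished = [c.request.order.slide_id for c in core.history]
        assert finished == ["a", "b", "c"]
        assert all(c.request.status == "succeeded" for c in core.history)

    def test_permanent_failure_attempted_exactly_three_times(self, registry):
        calls = []

        def broken(request, spec):
            calls.append(request.order.slide_id)
            raise RuntimeError("backend down")

        core = AiDssCore(registry, broken, aa_sender)
        core.enqueue(make_request("breast-tumor-resnet34.tcga-brca", tag="x"))
        core.drain()
        assert calls == ["x", "x", "x"]
        assert core.history[-1].request.status == "failed"
        assert core.history[-1].request.attempts == 3

    def test_failing_request_does_not_block_the_queue(self, registry,
                                                      canned_processor):
        def flaky(request, spec):
            if request.order.slide_id == "bad":
                raise RuntimeError("always fails")
            return canned_processor(request, spec)

        core = AiDssCore(registry, flaky, aa_sender)
        model = "breast-tumor-resnet34.tcga-brca"
        core.enqueue(make_request(model, tag="bad"))
        core.enqueue(make_request(model, tag="good"))
        core.drain()
        statuses = {c.request.order.slide_id: c.request.status
                    for c in core.history}
        assert statuses == {"bad": "failed", "good": "succeeded"}
        # the failing request burned its 3 attempts before "good" ran
        assert [c.request.order.slide_id for c in core.history] == \
            ["bad", "good"]

    def test_two_failures_then_success_ends_with_three_attempts(
            self, registry, canned_processor):
        countdown = [2]

        def flaky(request, spec):
            if countdown[0] > 0:
                countdown[0] -= 1
                raise RuntimeError("transient")
            return canned_processor(request, spec)

        core = AiDssCore(registry, flaky, aa_sender)
        core.enqueue(make_request("breast-tumor-resnet34.tcga-brca"))
        core.drain()
        done = core.history[-1].request
        assert done.status == "succeeded"
        assert done.attempts == 3

    def test_no_request_ever_runs_a_fourth_time(self, registry):
        attempts_seen = []

        def broken(request, spec):
            attempts_seen.append(request.attempts)
            raise RuntimeError("down")

        core = AiDssCore(registry, broken, aa_sender)
        for i in range(3):
            core.enqueue(make_request("colorectal-resnet34.penn", tag=str(i)))
        core.drain()
        assert max(attempts_seen) == 3
        assert len(attempts_seen) == 9  # 3 requests x 3 attempts

    def test_negative_lis_ack_counts_as_failed_attempt(self, registry,
                                                       canned_processor):
        def ae_sender(message, request):
            return build_ack(message, "AE")

        core = AiDssCore(registry, canned_processor, ae_sender)
        core.enqueue(make_request("breast-tumor-resnet34.tcga-brca"))
        core.drain()
        done = core.history[-1].request
        assert done.status == "failed" and done.attempts == 3

    def test_successful_request_records_both_timing_counters(
            self, registry, canned_processor):
        core = AiDssCore(registry, canned_processor, aa_sender)
        core.enqueue(make_request("breast-tumor-resnet34.tcga-brca"))
        core.drain()
        timing = core.history[-1].timing
        assert timing is not None
        assert 0 <= timing.inference_and_project_seconds \
            <= timing.total_request_seconds

    def test_unknown_model_surfaces_as_failed_attempts(self, registry):
        core = AiDssCore(registry, result_sender=aa_sender)
        core.enqueue(make_request("no-such-model"))
        core.drain()
        assert core.history[-1].request.status == "failed"


class TestDefaultModeTrigger:
    def test_one_request_per_matching_model(self, registry):
        requests = default_mode_trigger(
            registry, "/wsi/b1.svs", "breast", "H&E"
        )
        assert len(requests) == 2  # tumor + lymphocyte models
        assert all(r.mode == "default" for r in requests)
        assert len({r.order.model_name for r in requests}) == len(requests)

    def test_no_match_yields_empty_list_not_error(self, registry):
        assert default_mode_trigger(registry, "/wsi/x", "colon", "IHC") == []

    def test_each_trigger_is_a_single_spm_message(self, registry):
        requests = default_mode_trigger(
            registry, "/wsi/c.svs", "colorectal", "H&E"
        )
        assert len(requests) == 3
        for r in requests:
            msg = build_oml_o33(r.order, mode=r.mode)
            assert len(msg.segments_named("SPM")) == 1


class TestSocketFrontEnd:
    def test_burst_is_acked_before_first_completion(self, registry,
                                                    canned_processor):
        from histolink.fixtures import MockApLis

        def slow(request, spec):
            return canned_processor(request, spec, delay=0.5)

        core = AiDssCore(registry, slow, aa_sender)
        server = AiDssServer(core)
        server.start()
        lis = MockApLis()
        try:
            order = OrderPayload(
                "m", "breast-tumor-resnet34.tcga-brca", "synthetic://s"
            )
            acks = [lis.send_order(order, server.endpoint) for _ in range(5)]
            completed_at_last_ack = len(core.history)
        finally:
            server.stop()
        assert all(ack_code(a) == "AA" for a in acks)
        assert completed_at_last_ack < 5

    def test_send_result_times_out_on_silent_peer(self, registry,
                                                  canned_processor,
                                                  slide_reader):
        from histolink.fixtures import MockApLis
        from histolink.hl7 import build_oul_r21
        from histolink.server import send_result

        spec = registry.resolve("braf-attMIL-marugoto")
        bundle = run_inference(slide_reader, spec, seed=1)
        message = build_oul_r21(bundle, spec, control_id="T1")
        lis = MockApLis(scenario=["silent"])
        lis.start()
        try:
            with pytest.raises(DeliveryError):
                send_result(message, lis.endpoint, timeout=1.0)
        finally:
            lis.stop()

    def test_send_result_returns_peer_ack(self, registry, canned_processor,
                                          slide_reader):
        from histolink.fixtures import MockApLis
        from histolink.hl7 import build_oul_r21
        from histolink.server import send_result

        spec = registry.resolve("braf-attMIL-marugoto")
        bundle = run_inference(slide_reader, spec, seed=1)
        message = build_oul_r21(bundle, spec, control_id="T2")
        lis = MockApLis()
        lis.start()
        try:
            ack = send_result(message, lis.endpoint, timeout=5.0)
        finally:
            lis.stop()
        assert ack_code(ack) == "AA"
        assert ack.segment("MSA").field(2) == "T2"
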