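timestamp	event_type	actor	receiver	duration_s	present_ids
2024-03-01T08:00:00	dominance	A	B
2024-03-01T08:10:00	dominance	B	C
2024-03-01T08:20:00	dominance	A	C
2024-03-01T08:30:00	dominance	B	D
2024-03-01T08:40:00	dominance	A	D
2024-03-01T08:50:00	dominance	C	D
2024-03-01T10:00:00	groom	A	B	120	A;B;C;D
2024-03-01T10:30:00	proximity	B	C	60
2024-03-01T11:00:00	aggression	A	C
2024-03-01T12:00:00	groom	C	D	180	B;C;D
2024-03-02T09:00:00	presence	A			A;B;C;D;S
2024-03-02T09:05:00	aggression	A	C
2024-03-02T09:20:00	groom	A	B	60	A;B;C;D;S
2024-03-02T09:23:00	groom	A	C	60	A;B;C;D
2024-03-02T09:40:00	groom	B	A	90	A;B;C
2024-03-02T09:43:00	groom	C	S	60	A;C;S
2024-03-02T10:30:00	groom	A	D	60	A;B;D
2024-03-02T10:31:00	groom	D	A	30	A;D
2024-03-02T11:00:00	proximity	A	B	120
2024-03-02T12:00:00	groom	B	C	60	A;B;C
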