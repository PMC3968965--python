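# English stopword list for query construction (one term per line).
a
an
and
are
as
at
be
but
by
for
from
has
have
he
her
his
in
is
it
its
of
on
or
she
show
shows
suffers
that
the
their
they
this
to
was
were
will
with
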