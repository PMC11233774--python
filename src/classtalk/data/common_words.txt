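# Compact rank-ordered common English word list packaged for tests and
# examples. Production analyses should supply a corpus-derived
# 10,000-word list (one word per line, most common first).
the
be
to
of
and
a
in
that
have
i
it
for
not
on
with
he
as
you
do
at
this
but
his
by
from
they
we
say
her
she
or
an
will
my
one
all
would
there
their
what
so
up
out
if
about
who
get
which
go
me
when
make
can
like
time
no
just
him
know
take
people
into
year
your
good
some
could
them
see
other
than
then
now
look
only
come
its
over
think
also
back
after
use
two
how
our
work
first
well
way
even
new
want
because
any
these
give
day
most
us
is
was
are
were
been
being
am
has
had
did
does
done
said
went
got
made
came
took
saw
knew
thought
looked
wanted
used
found
gave
told
called
asked
need
feel
become
leave
put
mean
keep
let
begin
seem
help
talk
turn
start
show
hear
play
run
move
live
believe
hold
bring
happen
write
provide
sit
stand
lose
pay
meet
include
continue
set
learn
change
lead
understand
watch
follow
stop
create
speak
read
allow
add
spend
grow
open
walk
win
offer
remember
love
consider
appear
buy
wait
serve
die
send
expect
build
stay
fall
cut
reach
kill
remain
suggest
raise
pass
sell
require
report
decide
pull
eat
jump
laugh
sing
draw
paint
wash
clean
share
find
close
man
woman
child
children
world
school
state
family
student
group
country
problem
hand
part
place
case
week
company
system
program
question
right
government
number
night
point
home
water
room
mother
area
money
story
fact
month
lot
study
book
eye
job
word
business
issue
side
kind
head
house
service
friend
father
power
hour
game
line
end
member
law
car
city
community
name
president
team
minute
idea
kid
body
information
back
parent
face
others
level
office
door
health
person
art
war
history
party
result
morning
reason
research
girl
guy
moment
air
teacher
force
education
foot
boy
age
policy
process
music
market
sense
nation
plan
college
interest
death
experience
effect
class
control
care
field
development
role
effort
rate
heart
drug
show
leader
light
voice
wife
whole
police
mind
price
report
decision
son
view
relationship
town
road
arm
difference
value
building
action
model
season
society
tax
director
position
player
record
paper
space
ground
form
event
official
matter
center
couple
site
project
activity
star
table
court
oil
situation
cost
industry
figure
street
image
phone
data
picture
practice
piece
land
product
doctor
wall
patient
worker
news
test
movie
north
love
support
technology
bed
bird
dog
cat
fish
tree
flower
sun
moon
rain
snow
wind
fire
food
milk
bread
apple
ball
toy
block
card
color
circle
square
song
dance
hat
shoe
sock
shirt
coat
chair
desk
floor
window
box
bag
cup
plate
spoon
fork
knife
truck
train
bus
boat
plane
bike
farm
zoo
park
store
church
letter
paint
scissors
glue
crayon
pencil
pen
mirror
big
small
little
large
great
high
low
old
young
long
short
tall
wide
hot
cold
warm
cool
fast
slow
hard
soft
easy
early
late
near
far
full
empty
clean
dirty
light
dark
heavy
loud
quiet
happy
sad
angry
afraid
nice
kind
mean
funny
pretty
ugly
strong
weak
sick
fine
wet
dry
open
closed
same
different
important
able
bad
best
better
sure
true
real
free
black
white
red
blue
green
yellow
pink
brown
orange
purple
gray
next
last
few
many
much
more
less
very
too
really
still
again
always
never
sometimes
often
here
there
where
why
yes
please
thank
hello
okay
today
tomorrow
yesterday
soon
down
around
between
under
against
during
without
before
through
both
each
while
should
must
might
may
shall
those
every
another
such
own
off
three
four
five
six
seven
eight
nine
ten
eleven
twelve
hundred
thousand
first
second
third
once
twice
together
along
away
inside
outside
above
below
behind
front
top
bottom
middle
left
corner
something
anything
nothing
everything
someone
anyone
everyone
nobody
somewhere
anywhere
everywhere
himself
herself
myself
yourself
itself
ourselves
themselves
maybe
almost
enough
quite
rather
instead
perhaps
already
yet
ever
else
thing
things
stuff
baby
brother
sister
grandma
grandpa
aunt
uncle
cousin
friend
neighbor
visit
listen
answer
call
carry
catch
throw
climb
count
cry
drink
drive
dress
fill
finish
fix
fly
forget
guess
hang
hate
hide
hit
hope
hurt
invite
join
kick
kiss
knock
miss
pick
plant
point
push
rest
ride
ring
save
shake
shout
sleep
smell
smile
spell
stick
surprise
taste
teach
touch
try
wake
wave
wear
wish
wonder
worry
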